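"""Phase-velocity dispersion curves and their CSV round trip.

A dispersion curve is phase velocity c(f) sampled on a strictly increasing
frequency grid.  Frequencies where no reliable spectral peak exists are kept
on the grid but marked missing (NaN) rather than guessed; downstream code
(model fitting, ensemble statistics) skips missing points.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["DispersionCurve", "read_curve_csv"]


@dataclass
class DispersionCurve:
    """Phase velocity versus frequency for one acquisition.

    Attributes
    ----------
    freqs : ndarray
        Strictly increasing frequencies, Hz.
    c : ndarray
        Phase velocity, m/s; NaN marks a missing estimate.
    quality : ndarray
        Per-frequency peak amplitude (arbitrary units) of the spectral
        maximum the velocity was read from; NaN where missing.
    """

    freqs: np.ndarray
    c: np.ndarray
    quality: np.ndarray = dataclass_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.quality is None:
            self.quality = np.full_like(self.c, np.nan)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.c.shape:
            raise ValidationError("freqs and c must be 1-D arrays of equal length")
        if self.freqs.size and np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("freqs must be strictly increasing")
        present = np.isfinite(self.c)
        if np.any(self.c[present] <= 0):
            raise ValidationError("phase velocities must be positive wherever present")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of frequencies with a present velocity estimate."""
        return np.isfinite(self.c)

    def select(self, f_lo: float, f_hi: float) -> tuple[np.ndarray, np.ndarray]:
        """Non-missing (f, c) pairs with f in the closed band [f_lo, f_hi]."""
        m = self.valid & (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return self.freqs[m], self.c[m]

    def resample(self, freqs: np.ndarray) -> "DispersionCurve":
        """Linearly interpolate present points onto a new frequency grid.

        Target frequencies outside the span of present points are marked
        missing; no extrapolation is performed.  Intended for putting curves
        from estimators with different native grids (e.g. FFT bins versus a
        configured grid) onto one shared grid for ensemble statistics.
        """
        freqs = np.asarray(freqs, dtype=float)
        m = self.valid
        c = np.full(freqs.shape, np.nan)
        q = np.full(freqs.shape, np.nan)
        if m.sum() >= 2:
            inside = (freqs >= self.freqs[m][0]) & (freqs <= self.freqs[m][-1])
            c[inside] = np.interp(freqs[inside], self.freqs[m], self.c[m])
            q[inside] = np.interp(freqs[inside], self.freqs[m], self.quality[m])
        elif m.sum() == 1:
            j = np.argmin(np.abs(freqs - self.freqs[m][0]))
            c[j], q[j] = self.c[m][0], self.quality[m][0]
        return DispersionCurve(freqs=freqs, c=c, quality=q)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "frequency_hz": self.freqs,
                "phase_velocity_mps": self.c,
                "quality": self.quality,
            }
        ).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> DispersionCurve:
    df = pd.read_csv(path)
    for col in ("frequency_hz", "phase_velocity_mps"):
        if col not in df.columns:
            raise ValidationError(f"curve CSV missing column {col!r}")
    quality = df["quality"].to_numpy() if "quality" in df.columns else None
    return DispersionCurve(
        freqs=df["frequency_hz"].to_numpy(),
        c=df["phase_velocity_mps"].to_numpy(),
        quality=quality,
    )
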