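"""Multi-acquisition robustness statistics for dispersion curves.

Repeated shear-wave acquisitions of the same medium yield an ensemble of
dispersion curves on a shared frequency grid.  Per-frequency mean, sample
standard deviation and the coefficient of variation ``CV = SD/MEAN * 100%``
summarize estimator robustness; the usable bandwidth is the contiguous
frequency run from a start frequency over which CV stays below a threshold
(30% by convention).  Comparing CV curves of two estimators on the same
ensemble quantifies their relative robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import DispersionCurve
from .errors import DomainError, ValidationError

__all__ = [
    "DispersionEnsemble",
    "SummaryStats",
    "aggregate",
    "usable_bandwidth",
    "compare_methods",
    "boxplot_summary",
]


@dataclass
class DispersionEnsemble:
    """Phase-velocity curves of several acquisitions on one frequency grid.

    ``curves[i, j]`` is the velocity of acquisition ``i`` at ``freqs[j]``,
    NaN where missing.
    """

    freqs: np.ndarray
    curves: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 2 or self.curves.shape[1] != self.freqs.size:
            raise ValidationError("curves must be [acquisition, frequency] on the shared grid")
        if self.curves.shape[0] < 2:
            raise ValidationError("an ensemble needs at least 2 acquisitions")

    @classmethod
    def from_curves(
        cls, curves: list[DispersionCurve], freqs: np.ndarray | None = None, label: str = ""
    ) -> "DispersionEnsemble":
        """Stack curves, resampling onto ``freqs`` (default: first curve's grid)."""
        if freqs is None:
            freqs = curves[0].freqs
        freqs = np.asarray(freqs, dtype=float)
        rows = []
        for cur in curves:
            if cur.freqs.shape == freqs.shape and np.allclose(cur.freqs, freqs):
                rows.append(cur.c)
            else:
                rows.append(cur.resample(freqs).c)
        return cls(freqs=freqs, curves=np.vstack(rows), label=label)


@dataclass
class SummaryStats:
    """Per-frequency ensemble summary: mean, SD, CV (%), and valid count."""

    freqs: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    n_valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.freqs,
                "mean_mps": self.mean,
                "sd_mps": self.sd,
                "cv_pct": self.cv,
                "n_valid": self.n_valid,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryStats":
        return cls(
            freqs=df["frequency_hz"].to_numpy(),
            mean=df["mean_mps"].to_numpy(),
            sd=df["sd_mps"].to_numpy(),
            cv=df["cv_pct"].to_numpy(),
            n_valid=df["n_valid"].to_numpy(),
        )


def aggregate(ens: DispersionEnsemble) -> SummaryStats:
    """Mean, sample SD (n-1 denominator) and CV per frequency.

    Frequencies with fewer than two non-missing acquisitions are marked
    missing in every statistic.
    """
    valid = np.isfinite(ens.curves)
    n = valid.sum(axis=0)
    mean = np.full(ens.freqs.size, np.nan)
    sd = np.full(ens.freqs.size, np.nan)
    cv = np.full(ens.freqs.size, np.nan)
    enough = n >= 2
    if np.any(enough):
        with np.errstate(invalid="ignore"):
            mean[enough] = np.nanmean(ens.curves[:, enough], axis=0)
            sd[enough] = np.nanstd(ens.curves[:, enough], axis=0, ddof=1)
        pos = enough & (mean > 0)
        cv[pos] = sd[pos] / mean[pos] * 100.0
    return SummaryStats(freqs=ens.freqs.copy(), mean=mean, sd=sd, cv=cv, n_valid=n)


def usable_bandwidth(
    stats: SummaryStats,
    f_start: float,
    cv_threshold: float = 30.0,
    contiguous: bool = True,
) -> float | None:
    """Largest frequency up to which CV stays below the threshold.

    With ``contiguous=True`` (default) returns the last frequency of the
    unbroken sub-threshold run starting at ``f_start``; a missing CV breaks
    the run.  With ``contiguous=False`` returns the largest grid frequency
    with sub-threshold CV at or above ``f_start``, ignoring interior
    exceedances.  Returns None if CV already meets or exceeds the threshold
    at ``f_start``.
    """
    idx = np.flatnonzero(stats.freqs >= f_start - 1e-9)
    if idx.size == 0:
        raise DomainError("f_start lies beyond the frequency grid")
    below = np.isfinite(stats.cv[idx]) & (stats.cv[idx] < cv_threshold)
    if not below[0]:
        return None
    if contiguous:
        run_end = np.argmin(below) - 1 if not below.all() else below.size - 1
        return float(stats.freqs[idx[run_end]])
    return float(stats.freqs[idx[np.flatnonzero(below)[-1]]])


def compare_methods(
    a: SummaryStats,
    b: SummaryStats,
    f_start: float | None = None,
    cv_threshold: float = 30.0,
) -> pd.DataFrame:
    """Per-frequency CV comparison table between two estimators.

    Columns: ``frequency_hz, cv_a, cv_b, cv_diff`` (= cv_b - cv_a) plus
    constant columns ``bandwidth_a``/``bandwidth_b`` holding each method's
    usable bandwidth from ``f_start`` (default: the first grid frequency).
    """
    if a.freqs.shape != b.freqs.shape or not np.allclose(a.freqs, b.freqs):
        raise DomainError("summaries must share an identical frequency grid")
    if f_start is None:
        f_start = float(a.freqs[0])
    bw_a = usable_bandwidth(a, f_start, cv_threshold)
    bw_b = usable_bandwidth(b, f_start, cv_threshold)
    return pd.DataFrame(
        {
            "frequency_hz": a.freqs,
            "cv_a": a.cv,
            "cv_b": b.cv,
            "cv_diff": b.cv - a.cv,
            "bandwidth_a": np.nan if bw_a is None else bw_a,
            "bandwidth_b": np.nan if bw_b is None else bw_b,
        }
    )


def boxplot_summary(values: np.ndarray, whisker_length: float = 1.5) -> dict:
    """Quartile/whisker/outlier summary matching the standard box-plot rule.

    Outliers are values above ``r3 + wl*(r3 - r1)`` or below
    ``r1 - wl*(r3 - r1)`` with ``wl = 1.5`` by default, where r1 and r3 are
    the 25th and 75th percentiles.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DomainError("no finite values to summarize")
    r1, med, r3 = np.percentile(vals, [25, 50, 75])
    iqr = r3 - r1
    lo, hi = r1 - whisker_length * iqr, r3 + whisker_length * iqr
    inside = vals[(vals >= lo) & (vals <= hi)]
    return {
        "q1": float(r1),
        "median": float(med),
        "q3": float(r3),
        "mean": float(vals.mean()),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": np.sort(vals[(vals < lo) | (vals > hi)]),
        "n": int(vals.size),
    }
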