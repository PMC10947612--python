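"""Baseline 2-D Fourier transform (2D-FT) dispersion estimation.

The classical frequency-wavenumber route: the spatiotemporal field is 2-D
Fourier transformed (optionally windowed and zero padded), the magnitude
spectrum is formed, and per-frequency wavenumber peaks are converted to
phase velocity ``c(f) = f / k`` (cyclic ``k``; equal to ``2*pi*f/k`` with
angular ``k``).  The dominant shear-wave mode is followed across frequency
by closest-velocity tracking rather than a bare per-row argmax, which keeps
the extractor on one mode when several ridges coexist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from ._peaks import parabolic_refine
from .curves import DispersionCurve
from .errors import NoSignalError, ValidationError
from .wavefield import WaveField

__all__ = [
    "FKSpectrum",
    "compute_fk",
    "normalize_per_frequency",
    "rightward_quadrant",
    "extract_curve_2dft",
]


@dataclass
class FKSpectrum:
    """Magnitude of the 2-D Fourier transform over the full signed f-k plane.

    ``M[f, k]`` is indexed by signed temporal frequency (rows) and signed
    spatial wavenumber (columns), both fftshifted to ascending order, in
    physical units (the DFT sum carries a ``dx*dt`` weight).  Under the
    package sign convention rightward-travelling energy lives where ``f``
    and ``k`` have opposite signs.
    """

    M: np.ndarray
    freq_grid: np.ndarray
    k_grid: np.ndarray
    pad_factors: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.M.shape != (self.freq_grid.size, self.k_grid.size):
            raise ValidationError("M dimensions must match the grids")
        if np.any(self.M < 0) or not np.all(np.isfinite(self.M)):
            raise ValidationError("M must be finite and non-negative")


def compute_fk(
    field: WaveField, pad_t: int = 1, pad_x: int = 4, window: str = "none"
) -> FKSpectrum:
    """f-k magnitude spectrum of a field.

    Parameters
    ----------
    pad_t, pad_x : int
        Zero-padding factors (>= 1) along time and space; padding refines
        the bin spacing without adding information.  The wavenumber axis is
        padded by default because sub-bin peak accuracy there directly
        limits velocity accuracy; the frequency axis is left at native
        resolution (dispersion curves are resampled onto the analysis grid
        downstream, and between-bin evaluation only interpolates).
    window : str
        ``'none'`` (default) or ``'tukey'`` (alpha=0.1 taper on both axes)
        to reduce spectral leakage from the record edges.
    """
    if pad_t < 1 or pad_x < 1:
        raise ValidationError("pad factors must be >= 1")
    if window not in ("none", "tukey"):
        raise ValidationError("window must be 'none' or 'tukey'")
    v = field.v
    if window == "tukey":
        v = v * np.outer(windows.tukey(field.nx, 0.1), windows.tukey(field.nt, 0.1))
    nkx, nft = field.nx * pad_x, field.nt * pad_t
    spec = np.fft.fft2(v, s=(nkx, nft))  # axes: (k, f)
    M = np.fft.fftshift(np.abs(spec)).T * field.dx * field.dt  # -> [f, k]
    freqs = np.fft.fftshift(np.fft.fftfreq(nft, d=field.dt))
    ks = np.fft.fftshift(np.fft.fftfreq(nkx, d=field.dx))
    return FKSpectrum(M=M, freq_grid=freqs, k_grid=ks, pad_factors=(pad_t, pad_x))


def normalize_per_frequency(spec: FKSpectrum) -> FKSpectrum:
    """Divide each frequency row by its own maximum (zero rows untouched).

    Positive per-row scaling never moves peak locations, so extraction is
    unchanged; normalization only equalizes the display/quality scale
    across the band.
    """
    M = spec.M.copy()
    row_max = M.max(axis=1, keepdims=True)
    nz = row_max[:, 0] > 0
    M[nz] /= row_max[nz]
    return FKSpectrum(
        M=M, freq_grid=spec.freq_grid.copy(), k_grid=spec.k_grid.copy(),
        pad_factors=spec.pad_factors,
    )


def rightward_quadrant(spec: FKSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quadrant of rightward-travelling energy mapped to positive axes.

    Returns ``(Mq, f_pos, xi)`` where ``Mq[f, xi]`` holds the magnitudes at
    ``f > 0`` and spatial transform frequency ``k < 0`` re-indexed by the
    positive propagation wavenumber ``xi = -k`` in ascending order.
    """
    f_mask = spec.freq_grid > 0
    k_mask = spec.k_grid < 0
    Mq = spec.M[np.ix_(f_mask, k_mask)][:, ::-1]
    xi = -spec.k_grid[k_mask][::-1]
    return Mq, spec.freq_grid[f_mask], xi


def _row_candidates(row: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; falls back to the (first) argmax."""
    interior = (row[1:-1] > row[:-2]) & (row[1:-1] > row[2:])
    cand = np.flatnonzero(interior) + 1
    if cand.size == 0:
        cand = np.array([int(np.argmax(row))])
    return cand


def extract_curve_2dft(
    spec: FKSpectrum, min_quality: float = 0.1, track: bool = True
) -> DispersionCurve:
    """Extract the dominant-mode dispersion curve from an f-k spectrum.

    Candidate peaks are strict local maxima over wavenumber in the
    rightward quadrant.  With ``track=True`` (default) the mode is seeded
    at the frequency row with the greatest maximum and followed outward in
    both frequency directions, at each row accepting the candidate whose
    (sub-bin refined) phase velocity is closest to the previously accepted
    one.  ``track=False`` takes the per-row global argmax instead.  Rows
    whose peak amplitude falls below ``min_quality`` times the largest row
    peak are marked missing.
    """
    Mq, f_pos, xi = rightward_quadrant(spec)
    if not np.any(Mq > 0):
        raise NoSignalError("f-k spectrum contains no energy in the rightward quadrant")
    # exclude xi == 0 (infinite velocity)
    pos = xi > 0
    Mq, xi = Mq[:, pos], xi[pos]

    row_peaks = Mq.max(axis=1)
    floor = min_quality * row_peaks.max()
    usable = row_peaks >= max(floor, 0) if min_quality > 0 else row_peaks > 0
    usable &= row_peaks > 0

    c = np.full(f_pos.size, np.nan)
    quality = np.full(f_pos.size, np.nan)

    def refined_velocity(i: int, j: int) -> float:
        return f_pos[i] / parabolic_refine(xi, Mq[i], j)

    if not track:
        for i in np.flatnonzero(usable):
            j = int(np.argmax(Mq[i]))
            c[i] = refined_velocity(i, j)
            quality[i] = row_peaks[i]
    else:
        seed = int(np.argmax(row_peaks))
        j_seed = int(np.argmax(Mq[seed]))
        c[seed] = refined_velocity(seed, j_seed)
        quality[seed] = row_peaks[seed]
        for order in (range(seed + 1, f_pos.size), range(seed - 1, -1, -1)):
            prev_c = c[seed]
            for i in order:
                if not usable[i]:
                    continue
                cand = _row_candidates(Mq[i])
                cand_c = np.array([refined_velocity(i, j) for j in cand])
                pick = int(np.argmin(np.abs(cand_c - prev_c)))
                c[i] = cand_c[pick]
                quality[i] = Mq[i, cand[pick]]
                prev_c = c[i]
        c[~usable] = np.nan
        quality[~usable] = np.nan

    return DispersionCurve(freqs=f_pos, c=c, quality=quality)
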