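"""Spatiotemporal shear-wave field containers, I/O and spatial preprocessing.

The universal input of the package is a particle-velocity field ``v(x, t)``
sampled on uniform lateral and temporal grids, as produced by ultrafast
ultrasound tracking of an acoustic-radiation-force induced shear wave.  This
module defines the field containers, lossless HDF5/NPZ round-trip I/O, axial
averaging of a 3-D motion volume down to a 2-D field, lateral segment
selection, and frequency-wavenumber directional filtering used to separate
counter-propagating shear waves.

Sign convention
---------------
A rightward (increasing ``x``) travelling wave is ``cos(2*pi*(f*t - xi*x))``
with ``f, xi > 0``.  Under the forward DFT kernels ``exp(-i*2*pi*f*t)`` and
``exp(-i*2*pi*k*x)`` its energy lands in the two quadrants of the f-k plane
where the temporal and spatial transform frequencies have *opposite* signs.
The directional filter and the f-k estimators all share this convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

from .errors import DomainError, FormatError, ValidationError

__all__ = [
    "WaveField",
    "WaveVolume",
    "AcquisitionSet",
    "read_wavefield",
    "write_wavefield",
    "read_cohort",
    "write_cohort",
    "axial_average",
    "directional_filter",
    "select_lateral_segment",
]

MIN_SPATIAL_SAMPLES = 8
MIN_TEMPORAL_SAMPLES = 16


@dataclass
class WaveField:
    """A real particle-velocity matrix ``v[x, t]`` with uniform grids.

    Parameters
    ----------
    v : ndarray, shape (nx, nt)
        Particle velocity in m/s.
    dx, dt : float
        Lateral and temporal sampling steps in m and s.
    x0 : float
        Physical lateral position of the first sample, m.
    meta : dict
        Free-form provenance (source, seed, generator parameters, ...).
    """

    v: np.ndarray
    dx: float
    dt: float
    x0: float = 0.0
    meta: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 2:
            raise ValidationError("v must be a 2-D [space, time] matrix")
        if self.dx <= 0 or self.dt <= 0:
            raise ValidationError("grid steps dx and dt must be positive")
        nx, nt = self.v.shape
        if nx < MIN_SPATIAL_SAMPLES or nt < MIN_TEMPORAL_SAMPLES:
            raise ValidationError(
                f"field too small: need >= {MIN_SPATIAL_SAMPLES} spatial and "
                f">= {MIN_TEMPORAL_SAMPLES} temporal samples, got {nx} x {nt}"
            )
        if not np.all(np.isfinite(self.v)):
            raise ValidationError("field contains non-finite entries")

    @property
    def nx(self) -> int:
        return self.v.shape[0]

    @property
    def nt(self) -> int:
        return self.v.shape[1]

    @property
    def x(self) -> np.ndarray:
        """Physical lateral positions, m."""
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def t(self) -> np.ndarray:
        """Temporal grid starting at 0, s."""
        return self.dt * np.arange(self.nt)

    @property
    def nyquist(self) -> float:
        """Temporal Nyquist frequency, Hz."""
        return 0.5 / self.dt

    def energy(self) -> float:
        """Discrete signal energy ``sum(v**2) * dx * dt``."""
        return float(np.sum(self.v**2) * self.dx * self.dt)


@dataclass
class WaveVolume:
    """A 3-D particle-velocity array ``v[z, x, t]`` (depth, lateral, time)."""

    v: np.ndarray
    dz: float
    dx: float
    dt: float
    z0: float = 0.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 3:
            raise ValidationError("volume must be a 3-D [depth, space, time] array")
        if min(self.dz, self.dx, self.dt) <= 0:
            raise ValidationError("grid steps must be positive")
        if not np.all(np.isfinite(self.v)):
            raise ValidationError("volume contains non-finite entries")

    @property
    def z(self) -> np.ndarray:
        return self.z0 + self.dz * np.arange(self.v.shape[0])


@dataclass
class AcquisitionSet:
    """An ordered collection of acquisitions sharing identical grid steps."""

    fields: list[WaveField]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValidationError("acquisition set must be non-empty")
        dx0, dt0 = self.fields[0].dx, self.fields[0].dt
        for f in self.fields[1:]:
            if not (np.isclose(f.dx, dx0) and np.isclose(f.dt, dt0)):
                raise ValidationError("all acquisitions must share dx and dt")

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self) -> Iterator[WaveField]:
        return iter(self.fields)


# ---------------------------------------------------------------------------
# I/O: one field per file (HDF5 or NPZ), or one cohort per HDF5 file with
# groups /acq000, /acq001, ...  Datasets: v [nx, nt], scalars dx, dt, x0,
# and meta serialized as a JSON string.  Units are SI on disk.
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("v", "dx", "dt")


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("hdf5", "npz"):
            raise ValidationError(f"unknown dialect {dialect!r}")
        return dialect
    return "npz" if path.suffix == ".npz" else "hdf5"


def _field_from_mapping(data: dict) -> WaveField:
    for key in _REQUIRED_KEYS:
        if key not in data:
            raise FormatError(f"missing required dataset {key!r}")
    meta = data.get("meta", {})
    if isinstance(meta, (bytes, str, np.ndarray)):
        raw = meta.item() if isinstance(meta, np.ndarray) else meta
        if isinstance(raw, bytes):
            raw = raw.decode()
        meta = json.loads(raw) if raw else {}
    return WaveField(
        v=np.asarray(data["v"], dtype=float),
        dx=float(np.asarray(data["dx"])),
        dt=float(np.asarray(data["dt"])),
        x0=float(np.asarray(data.get("x0", 0.0))),
        meta=meta,
    )


def write_wavefield(field: WaveField, path: str | Path, dialect: str | None = None) -> None:
    """Write a field to ``path`` in the package's HDF5 or NPZ layout."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    meta_json = json.dumps(field.meta)
    if dialect == "npz":
        np.savez(path, v=field.v, dx=field.dx, dt=field.dt, x0=field.x0, meta=meta_json)
    else:
        with h5py.File(path, "w") as h5:
            _write_group(h5, field, meta_json)


def _write_group(grp, field: WaveField, meta_json: str) -> None:
    grp.create_dataset("v", data=field.v)
    grp.create_dataset("dx", data=field.dx)
    grp.create_dataset("dt", data=field.dt)
    grp.create_dataset("x0", data=field.x0)
    grp.create_dataset("meta", data=meta_json)


def read_wavefield(path: str | Path, dialect: str | None = None) -> WaveField:
    """Read a single field written by :func:`write_wavefield`.

    Raises
    ------
    FormatError
        If a required dataset (``v``, ``dx``, ``dt``) is absent.
    ValidationError
        If the stored field violates the container invariants.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    dialect = _infer_dialect(path, dialect)
    if dialect == "npz":
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    else:
        with h5py.File(path, "r") as h5:
            data = {k: h5[k][()] for k in h5.keys()}
    return _field_from_mapping(data)


def write_cohort(cohort: AcquisitionSet, path: str | Path) -> None:
    """Write a cohort to one HDF5 file, one group per acquisition."""
    with h5py.File(path, "w") as h5:
        h5.attrs["label"] = cohort.label
        for i, f in enumerate(cohort.fields):
            grp = h5.create_group(f"acq{i:03d}")
            _write_group(grp, f, json.dumps(f.meta))


def read_cohort(path: str | Path) -> AcquisitionSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fields = []
    with h5py.File(path, "r") as h5:
        label = str(h5.attrs.get("label", ""))
        for name in sorted(h5.keys()):
            grp = h5[name]
            data = {k: grp[k][()] for k in grp.keys()}
            fields.append(_field_from_mapping(data))
    if not fields:
        raise FormatError(f"cohort file {path} contains no acquisition groups")
    return AcquisitionSet(fields=fields, label=label)


# ---------------------------------------------------------------------------
# Spatial preprocessing
# ---------------------------------------------------------------------------


def axial_average(vol: WaveVolume, center_z: float, window: float) -> WaveField:
    """Average a motion volume over a closed axial window into one field.

    Emulates the standard preprocessing step of averaging tracked particle
    velocity over a few millimetres in depth around the push focus before
    dispersion analysis.  Samples exactly on the window boundary are included.
    """
    if window <= 0:
        raise DomainError("axial window must be positive")
    z = vol.z
    lo, hi = center_z - window / 2, center_z + window / 2
    mask = (z >= lo) & (z <= hi)
    if not np.any(mask):
        raise DomainError(
            f"axial window [{lo}, {hi}] m does not intersect the depth grid "
            f"[{z[0]}, {z[-1]}] m"
        )
    v = vol.v[mask].mean(axis=0)
    return WaveField(v=v, dx=vol.dx, dt=vol.dt, x0=0.0)


def select_lateral_segment(field: WaveField, x_start: float, x_end: float) -> WaveField:
    """Restrict a field to the lateral samples inside ``[x_start, x_end]``.

    The interval is closed on physical coordinates with a half-sample
    (``dx/2``) tolerance on both edges, so a grid point lying within half a
    step outside the requested interval is still retained.  ``x0`` of the
    output maps the first retained sample to its original physical position.
    """
    if x_start >= x_end:
        raise DomainError("x_start must be strictly less than x_end")
    x = field.x
    tol = field.dx / 2
    mask = (x >= x_start - tol) & (x <= x_end + tol)
    if not np.any(mask):
        raise DomainError("requested lateral segment does not intersect the grid")
    idx = np.flatnonzero(mask)
    out = WaveField(
        v=field.v[idx[0] : idx[-1] + 1].copy(),
        dx=field.dx,
        dt=field.dt,
        x0=float(x[idx[0]]),
        meta=dict(field.meta),
    )
    return out


def _smoothed_step(freqs: np.ndarray, width: float) -> np.ndarray:
    """Raised-cosine smoothed unit step: 0 below -width, 1 above +width.

    Satisfies h(z) + h(-z) = 1, so direction masks built from it partition
    the f-k plane exactly in amplitude.
    """
    if width == 0:
        return (freqs > 0).astype(float) + 0.5 * (freqs == 0)
    h = 0.5 * (1.0 + np.sin(np.pi * freqs / (2 * width)))
    h[freqs <= -width] = 0.0
    h[freqs >= width] = 1.0
    return h


def directional_filter(
    field: WaveField, direction: str, taper_width: float = 0.1
) -> WaveField:
    """Retain only one propagation direction via an f-k quadrant mask.

    ``direction='rightward'`` keeps the two quadrants of the 2-D Fourier
    plane where temporal frequency and spatial wavenumber have opposite
    signs (see the module sign convention); ``'leftward'`` keeps the other
    pair.  A raised-cosine taper of relative half-width ``taper_width``
    (fraction of each axis' Nyquist extent) smooths the quadrant boundaries.
    The rightward and leftward masks sum to one everywhere, so the two
    outputs reconstruct the input field exactly in amplitude.
    """
    if direction not in ("rightward", "leftward"):
        raise ValidationError(f"direction must be 'rightward' or 'leftward', got {direction!r}")
    if not 0 <= taper_width <= 0.5:
        raise ValidationError("taper_width must lie in [0, 0.5]")

    ft = np.fft.fftfreq(field.nt, d=field.dt)  # temporal frequency
    kx = np.fft.fftfreq(field.nx, d=field.dx)  # spatial frequency
    h_f = _smoothed_step(ft, taper_width * field.nyquist)
    h_k = _smoothed_step(kx, taper_width * (0.5 / field.dx))
    # rightward: opposite signs of (f, k); leftward: equal signs
    H_f = h_f[None, :]
    H_k = h_k[:, None]
    if direction == "rightward":
        mask = H_f * (1.0 - H_k) + (1.0 - H_f) * H_k
    else:
        mask = H_f * H_k + (1.0 - H_f) * (1.0 - H_k)

    spec = np.fft.fft2(field.v)
    filtered = np.fft.ifft2(spec * mask).real
    return WaveField(v=filtered, dx=field.dx, dt=field.dt, x0=field.x0, meta=dict(field.meta))
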