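"""Viscoelastic rheological models, dispersion-curve fitting, and convergence.

Zener (standard linear solid) model: a dashpot ``eta`` in series with a
spring ``E2``, in parallel with a spring ``E1``; its stress-strain law

    sigma + tau_s * dsigma/dt = E1 * (eps + tau_e * deps/dt)

with relaxation time ``tau_s = eta/E2`` and retardation time
``tau_e = eta/E1 + eta/E2`` leads to the frequency-dependent shear-wave
phase velocity (omega = 2*pi*f, density rho)

    c(omega) = sqrt( 2*(A**2 + B**2)
                     / (3*rho*(E2**2 + eta**2*omega**2) * (B + sqrt(A**2+B**2))) )

with ``A = eta*omega*E2**2`` and ``B = E1*E2**2 + eta**2*omega**2*(E1+E2)``.
The factor 3 converts Young's moduli to shear moduli for an incompressible
solid (G = E/3).  As ``E2 -> inf`` the model degenerates to Kelvin-Voigt
(spring ``E1`` parallel to dashpot ``eta``), whose phase velocity is

    c(omega) = sqrt( 2*(E1**2 + omega**2*eta**2)
                     / (3*rho*(E1 + sqrt(E1**2 + omega**2*eta**2))) ).

Parameters are estimated by nonlinear least squares on the measured curve,
``min sum_f (c_model(f) - c_hat(f))**2``; the minimized sum is reported as
the norm of residuals (NoR, m^2/s^2).  Fits with NoR above 1 m^2/s^2 are
flagged unreliable.  Because the objective is non-convex and ``E2`` is
weakly identified on narrow bands, optimization runs in log-parameter
space from multiple seeded Latin-hypercube starts and keeps the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .curves import DispersionCurve
from .errors import DomainError, OptimizationError, ValidationError

__all__ = [
    "ZenerParams",
    "KVParams",
    "FitResult",
    "ConvergenceTrace",
    "zener_phase_velocity",
    "kv_phase_velocity",
    "zener_complex_modulus",
    "kv_complex_modulus",
    "fit_model",
    "convergence_analysis",
]

RELIABLE_NOR = 1.0  # m^2/s^2; fits with larger residual norm are distrusted

# optimization bounds (log-space search): E in Pa, eta in Pa*s
_BOUNDS = {
    "zener": (np.log([1e2, 1e2, 1e-2]), np.log([1e6, 1e9, 1e2])),
    "kv": (np.log([1e2, 1e-2]), np.log([1e6, 1e2])),
}


@dataclass(frozen=True)
class ZenerParams:
    """Zener (standard linear solid) parameters, SI units."""

    E1: float  # Pa
    E2: float  # Pa
    eta: float  # Pa*s
    rho: float = 1000.0  # kg/m^3, soft-tissue convention

    def __post_init__(self) -> None:
        if min(self.E1, self.E2, self.eta, self.rho) <= 0:
            raise DomainError("all Zener parameters must be strictly positive")

    @property
    def tau_sigma(self) -> float:
        """Relaxation time eta/E2, s."""
        return self.eta / self.E2

    @property
    def tau_eps(self) -> float:
        """Retardation time eta/E1 + eta/E2, s (always >= tau_sigma)."""
        return self.eta / self.E1 + self.eta / self.E2


@dataclass(frozen=True)
class KVParams:
    """Kelvin-Voigt parameters, SI units."""

    E1: float  # Pa
    eta: float  # Pa*s
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.E1, self.eta, self.rho) <= 0:
            raise DomainError("all Kelvin-Voigt parameters must be strictly positive")


@dataclass
class FitResult:
    """Outcome of one rheological fit over a frequency band."""

    params: ZenerParams | KVParams
    nor: float  # squared L2 norm of velocity residuals, m^2/s^2
    f_lo: float
    f_hi: float
    n_points: int
    converged_flag: bool
    reliable_flag: bool

    def as_report(self) -> dict:
        """JSON-ready report with moduli in kPa and viscosity in Pa*s."""
        p = self.params
        out = {
            "model": "zener" if isinstance(p, ZenerParams) else "kv",
            "E1_kpa": p.E1 / 1e3,
            "eta_pas": p.eta,
            "rho_kgm3": p.rho,
            "nor_m2s2": self.nor,
            "f_lo_hz": self.f_lo,
            "f_hi_hz": self.f_hi,
            "n_points": self.n_points,
            "converged": bool(self.converged_flag),
            "reliable": bool(self.reliable_flag),
        }
        if isinstance(p, ZenerParams):
            out["E2_kpa"] = p.E2 / 1e3
        return out


@dataclass
class ConvergenceTrace:
    """Fits over incrementally extended frequency windows sharing f_lo."""

    window_ends: np.ndarray
    fits: list[FitResult | None]
    plateau_end: float | None = None
    f_lo: float = 0.0
    plateau_tol: float = 0.05

    def to_frame(self):
        import pandas as pd

        rows = []
        for end, fit in zip(self.window_ends, self.fits):
            if fit is None:
                rows.append({"window_end_hz": end})
                continue
            p = fit.params
            rows.append(
                {
                    "window_end_hz": end,
                    "E1_kpa": p.E1 / 1e3,
                    "E2_kpa": p.E2 / 1e3 if isinstance(p, ZenerParams) else np.nan,
                    "eta_pas": p.eta,
                    "nor": fit.nor,
                    "reliable": fit.reliable_flag,
                }
            )
        return pd.DataFrame(rows)


def zener_phase_velocity(p: ZenerParams, f) -> np.ndarray | float:
    """Zener shear-wave phase velocity at frequency ``f`` (Hz), m/s.

    Strictly positive and non-decreasing in ``f``; at ``f = 0`` reduces to
    the elastic value ``sqrt(E1/(3*rho))``.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise DomainError("frequency must be non-negative")
    w = 2 * np.pi * f_arr
    A = p.eta * w * p.E2**2
    B = p.E1 * p.E2**2 + p.eta**2 * w**2 * (p.E1 + p.E2)
    mag = np.hypot(A, B)
    c2 = 2 * mag**2 / (3 * p.rho * (p.E2**2 + p.eta**2 * w**2) * (B + mag))
    out = np.sqrt(c2)
    return out if np.ndim(f) else float(out)


def kv_phase_velocity(p: KVParams, f) -> np.ndarray | float:
    """Kelvin-Voigt shear-wave phase velocity at frequency ``f`` (Hz), m/s."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise DomainError("frequency must be non-negative")
    w = 2 * np.pi * f_arr
    mag = np.hypot(p.E1, w * p.eta)
    out = np.sqrt(2 * (p.E1**2 + w**2 * p.eta**2) / (3 * p.rho * (p.E1 + mag)))
    return out if np.ndim(f) else float(out)


def zener_complex_modulus(p: ZenerParams, f) -> np.ndarray:
    """Complex Young's modulus E* = E1 (1 + i w tau_e) / (1 + i w tau_s)."""
    w = 2 * np.pi * np.asarray(f, dtype=float)
    return p.E1 * (1 + 1j * w * p.tau_eps) / (1 + 1j * w * p.tau_sigma)


def kv_complex_modulus(p: KVParams, f) -> np.ndarray:
    """Complex Young's modulus E* = E1 + i w eta."""
    w = 2 * np.pi * np.asarray(f, dtype=float)
    return p.E1 + 1j * w * p.eta


def _model_velocity(model: str, log_theta: np.ndarray, f: np.ndarray, rho: float):
    theta = np.exp(log_theta)
    if model == "zener":
        return zener_phase_velocity(ZenerParams(theta[0], theta[1], theta[2], rho), f)
    return kv_phase_velocity(KVParams(theta[0], theta[1], rho), f)


def fit_model(
    curve: DispersionCurve,
    model: str = "zener",
    f_lo: float = 150.0,
    f_hi: float = 1500.0,
    rho: float = 1000.0,
    starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Fit a rheological model to a dispersion curve by multistart NLSQ.

    Minimizes ``sum_f (c_model(f) - c_hat(f))**2`` over the non-missing
    curve points inside the closed band ``[f_lo, f_hi]``; missing points
    are skipped, never interpolated.  ``starts`` Latin-hypercube starting
    points are drawn (seeded) in the log-parameter box and the best local
    optimum is returned; its minimized sum is the norm of residuals.

    Raises
    ------
    DomainError
        Fewer than 4 (Zener) / 3 (Kelvin-Voigt) usable points in band.
    OptimizationError
        Every start failed (pathological input).
    """
    if model not in ("zener", "kv"):
        raise ValidationError("model must be 'zener' or 'kv'")
    if f_lo >= f_hi:
        raise DomainError("f_lo must be below f_hi")
    f, c = curve.select(f_lo, f_hi)
    n_min = 4 if model == "zener" else 3
    if f.size < n_min:
        raise DomainError(
            f"{model} fit needs >= {n_min} non-missing points in [{f_lo}, {f_hi}] Hz, "
            f"got {f.size}"
        )
    lb, ub = _BOUNDS[model]
    sampler = qmc.LatinHypercube(d=lb.size, seed=seed)
    x0s = lb + sampler.random(starts) * (ub - lb)

    def resid(log_theta):
        return _model_velocity(model, log_theta, f, rho) - c

    best = None
    any_ok = False
    for x0 in x0s:
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        any_ok = any_ok or sol.success
        nor = float(np.sum(sol.fun**2))
        if best is None or nor < best[0]:
            best = (nor, sol.x, sol.success)
    if best is None:
        raise OptimizationError("all optimization starts failed")
    nor, log_theta, success = best
    theta = np.exp(log_theta)
    params: ZenerParams | KVParams
    if model == "zener":
        params = ZenerParams(theta[0], theta[1], theta[2], rho)
    else:
        params = KVParams(theta[0], theta[1], rho)
    return FitResult(
        params=params,
        nor=nor,
        f_lo=f_lo,
        f_hi=f_hi,
        n_points=int(f.size),
        converged_flag=bool(any_ok and success),
        reliable_flag=bool(nor <= RELIABLE_NOR),
    )


def convergence_analysis(
    curve: DispersionCurve,
    model: str = "zener",
    f_lo: float = 200.0,
    first_end: float = 300.0,
    step: float = 25.0,
    max_end: float = 1100.0,
    rho: float = 1000.0,
    plateau_tol: float = 0.05,
    starts: int = 16,
    seed: int = 0,
) -> ConvergenceTrace:
    """Fit over incrementally widened bands and locate the parameter plateau.

    The model is fitted on ``[f_lo, end]`` for ``end = first_end,
    first_end + step, ..., max_end``.  ``plateau_end`` is the smallest
    window end from which, for every subsequent window, all parameters stay
    within ``plateau_tol`` (relative) of their final-window values *and*
    the fit is reliable (NoR <= 1 m^2/s^2); absent (None) if never
    achieved.  Per-window fit failures are recorded as None, not raised.
    """
    if max_end < first_end:
        raise DomainError("max_end must be >= first_end")
    ends = np.arange(first_end, max_end + step / 2, step)
    fits: list[FitResult | None] = []
    for end in ends:
        try:
            fits.append(
                fit_model(curve, model=model, f_lo=f_lo, f_hi=float(end),
                          rho=rho, starts=starts, seed=seed)
            )
        except (DomainError, OptimizationError):
            fits.append(None)

    plateau_end: float | None = None
    final = fits[-1]
    if final is not None:
        names = ("E1", "E2", "eta") if model == "zener" else ("E1", "eta")
        ref = np.array([getattr(final.params, n) for n in names])
        ok = np.zeros(ends.size, dtype=bool)
        for i, fit in enumerate(fits):
            if fit is None or fit.nor > RELIABLE_NOR:
                continue
            vals = np.array([getattr(fit.params, n) for n in names])
            ok[i] = np.all(np.abs(vals - ref) <= plateau_tol * np.abs(ref))
        # smallest end from which every later window stays within band
        suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
        hits = np.flatnonzero(suffix_ok)
        if hits.size:
            plateau_end = float(ends[hits[0]])

    return ConvergenceTrace(
        window_ends=ends, fits=fits, plateau_end=plateau_end,
        f_lo=f_lo, plateau_tol=plateau_tol,
    )
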