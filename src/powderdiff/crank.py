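"""Crank's solution for diffusion into a sphere, and least-squares D_eff fitting.

For Fickian diffusion into a sphere of radius ``R`` held at constant surface
concentration, the fractional uptake (total amount entered, relative to
equilibrium) is the classical series

    U(tau) = 1 - (6/pi^2) * sum_{n>=1} (1/n^2) exp(-n^2 pi^2 tau),

with ``tau = D t / R^2`` the dimensionless time.  The measured quantity in a
rehydration experiment is the min-max normalized mean fluorescence intensity
of a particle, which starts at a nonzero baseline ``i0`` (the dye has already
penetrated somewhat by the first capture) and plateaus at ``i_inf <= 1``; the
model trace is therefore the affine embedding

    I(t) = i0 + (i_inf - i0) * U(D t / R^2).

``fit_deff`` estimates ``(D, i0, i_inf)`` from an intensity trace by
least squares, profiling the affine pair out in closed form and multi-starting
the remaining 1-D search over ``log10 D``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["CrankFit", "crank_uptake", "slice_uptake", "predict_trace", "fit_deff"]

_MAX_TERMS = 10_000


def _n_terms_for(tau: float) -> int:
    """Adaptive truncation: enough terms that the first omitted one is
    negligible (exp(-n^2 pi^2 tau) tiny), never fewer than 10."""
    if tau <= 0:
        return 10
    return int(min(_MAX_TERMS, max(10, np.ceil(4.0 / np.sqrt(np.pi**2 * tau)))))


def crank_uptake(tau, n_terms: int | None = None):
    """Fractional uptake of a sphere at dimensionless time ``tau = D t / R^2``.

    Parameters
    ----------
    tau : float or array
        Dimensionless time, >= 0.
    n_terms : int, optional
        Series truncation; by default chosen adaptively from ``tau`` so the
        truncation error is below 1e-9.

    Returns
    -------
    float or array in [0, 1], exactly 0 at ``tau = 0`` (since
    ``sum 1/n^2 = pi^2/6``) and -> 1 as ``tau -> inf``.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be non-negative")
    scalar = tau_arr.ndim == 0
    tau_arr = np.atleast_1d(tau_arr)

    out = np.zeros_like(tau_arr)
    for i, t in enumerate(tau_arr):
        if t == 0.0:
            out[i] = 0.0
            continue
        nt = n_terms if n_terms is not None else _n_terms_for(t)
        n = np.arange(1, nt + 1, dtype=float)
        s = np.sum(np.exp(-(n**2) * np.pi**2 * t) / n**2)
        out[i] = 1.0 - 6.0 / np.pi**2 * s
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def slice_uptake(tau, n_terms: int | None = None):
    """Mean concentration over the equatorial cross-section of the sphere.

    A confocal slice through the particle centre averages the concentration
    over the equatorial disc rather than the sphere volume.  Integrating the
    radial profile over the disc gives the closed form

        S(tau) = 1 - (8/pi^2) * sum_{n odd} (1/n^2) exp(-n^2 pi^2 tau),

    (sum over odd n of 1/n^2 = pi^2/8, so S(0) = 0).  S rises more slowly
    than the volume uptake at early times because the slice under-weights
    the fast-saturating outer shell; fitting the volume kernel to slice-
    averaged data underestimates D severalfold, so image-derived traces
    should be fitted with this kernel.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be non-negative")
    scalar = tau_arr.ndim == 0
    tau_arr = np.atleast_1d(tau_arr)
    out = np.zeros_like(tau_arr)
    for i, t in enumerate(tau_arr):
        if t == 0.0:
            continue
        nt = n_terms if n_terms is not None else _n_terms_for(t)
        n = np.arange(1, 2 * nt, 2, dtype=float)  # odd n only
        s = np.sum(np.exp(-(n**2) * np.pi**2 * t) / n**2)
        out[i] = 1.0 - 8.0 / np.pi**2 * s
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


_KERNELS = {"sphere": crank_uptake, "slice": slice_uptake}


@dataclass
class CrankFit:
    """A fitted spherical-uptake model for one particle.

    Attributes
    ----------
    deff_m2_s : float
        Effective diffusion coefficient (m^2/s), > 0.
    radius_m : float
        Particle radius R (m) used in the fit (from the equivalent diameter).
    i0, i_inf : float
        Baseline and plateau of the normalized intensity, 0 <= i0 < i_inf <= 1.
    n_terms : int
        Series truncation floor used when evaluating the model.
    sse : float
        Sum of squared residuals at the optimum.
    n_points : int
        Number of time points fitted.
    converged : bool
    """

    deff_m2_s: float
    radius_m: float
    i0: float
    i_inf: float
    n_terms: int = 10
    sse: float = np.nan
    n_points: int = 0
    converged: bool = False
    geometry: str = "sphere"  # "sphere" (volume uptake) or "slice" (equatorial)

    def __post_init__(self) -> None:
        if self.geometry not in _KERNELS:
            raise ValueError(f"geometry must be one of {sorted(_KERNELS)}")
        if not self.deff_m2_s > 0:
            raise ValueError("deff_m2_s must be positive")
        if not self.radius_m > 0:
            raise ValueError("radius_m must be positive")
        if not (0.0 <= self.i0 < self.i_inf <= 1.0):
            raise ValueError("require 0 <= i0 < i_inf <= 1")


def predict_trace(fit: CrankFit, times_s) -> np.ndarray:
    """Model-predicted normalized intensity at the given times (seconds)."""
    t = np.asarray(times_s, dtype=float)
    tau = fit.deff_m2_s * t / fit.radius_m**2
    kernel = _KERNELS[fit.geometry]
    return fit.i0 + (fit.i_inf - fit.i0) * np.atleast_1d(kernel(tau))


def _profiled_sse(log10_d: float, times: np.ndarray, y: np.ndarray,
                  radius_m: float, kernel=crank_uptake) -> tuple[float, float, float]:
    """SSE minimized over (i0, i_inf) in closed form for a fixed D.

    The model is linear in (i0, i_inf) given the uptake curve u(t):
    y ~ i0 (1 - u) + i_inf u.  The unconstrained linear solution is clipped
    into the box 0 <= i0 < i_inf <= 1 when it falls outside.
    """
    d = 10.0 ** log10_d
    u = np.atleast_1d(kernel(d * times / radius_m**2))
    A = np.column_stack([1.0 - u, u])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    i0, i_inf = coef
    i0 = float(np.clip(i0, 0.0, 1.0))
    i_inf = float(np.clip(i_inf, 0.0, 1.0))
    if i_inf <= i0:  # degenerate (flat) solution; keep an ordered pair
        mid = 0.5 * (i0 + i_inf)
        i0, i_inf = max(0.0, mid - 5e-4), min(1.0, mid + 5e-4)
    resid = y - (i0 * (1.0 - u) + i_inf * u)
    return float(resid @ resid), i0, i_inf


def fit_deff(
    trace,
    radius_m: float,
    d_grid_m2_s=None,
    n_starts: int = 9,
    geometry: str = "sphere",
) -> CrankFit:
    """Least-squares estimate of (D, i0, i_inf) from an intensity trace.

    Parameters
    ----------
    trace : IntensityTrace or any object with ``times_s`` and
        ``mean_rel_intensity`` attributes (>= 4 points).
    radius_m : float
        Sphere radius, from the particle's equivalent diameter.
    d_grid_m2_s : array, optional
        Multi-start grid for D; default 9 log-spaced values over
        1e-15 ... 1e-11 m^2/s (spans the plausible range for water/dye in
        dense protein matrices).

    geometry : {"sphere", "slice"}
        Uptake kernel.  "sphere" is the volume-average fractional uptake
        (appropriate when the measurement integrates the whole particle);
        "slice" is the equatorial-disc average (appropriate for a confocal
        slice through the particle centre, which is what the imaging
        pipeline measures).

    Each start runs a bounded 1-D minimization of the profiled SSE over
    log10(D) in a +/- 1.5-decade bracket; the best of all starts wins.
    """
    times = np.asarray(trace.times_s, dtype=float)
    y = np.asarray(trace.mean_rel_intensity, dtype=float)
    if len(times) < 4:
        raise ValueError(
            f"need >= 4 time points to fit, got {len(times)}"
            + (f" (track {trace.track_id})" if hasattr(trace, "track_id") else "")
        )
    if not radius_m > 0:
        raise ValueError("radius_m must be positive")
    if np.ptp(y) == 0:
        raise ValueError(
            "all-constant intensity trace: D is unidentifiable"
            + (f" (track {trace.track_id})" if hasattr(trace, "track_id") else "")
        )

    if d_grid_m2_s is None:
        d_grid_m2_s = np.logspace(-15, -11, n_starts)
    kernel = _KERNELS[geometry]

    best = None
    for d0 in d_grid_m2_s:
        lo, hi = np.log10(d0) - 1.5, np.log10(d0) + 1.5
        res = minimize_scalar(
            lambda z: _profiled_sse(z, times, y, radius_m, kernel)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if best is None or res.fun < best.fun:
            best = res
    sse, i0, i_inf = _profiled_sse(best.x, times, y, radius_m, kernel)
    return CrankFit(
        deff_m2_s=10.0 ** float(best.x),
        radius_m=float(radius_m),
        i0=i0,
        i_inf=i_inf,
        sse=sse,
        n_points=len(times),
        converged=bool(best.success),
        geometry=geometry,
    )
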