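"""Per-particle effective-diffusivity estimates and ensemble summaries.

Three estimates of D_eff are produced per particle:

* ``eq1`` — the area/time definition: initial particle area divided by the
  full diffusion time (the completion time from the endpoint rules).  This is
  a definition-by-construction, not the dimensional solution of the diffusion
  equation, but mirrors the traditional manual workflow.
* ``eq1_nm_refined`` — the eq1 value refined by a single-parameter
  Nelder-Mead minimization of sum_t (I_norm(t) - I_theor(t; D))^2 against the
  spherical-uptake model, with the baseline/plateau frozen at the trace's
  first/last values.
* ``crank_fit`` — the full least-squares fit (see :mod:`powderdiff.crank`).

Ensemble utilities: summary statistics, ordinary least-squares regression of
D on diameter (linear or quadratic), and averaging the regression over a
measured particle-size distribution to obtain a powder-level D_eff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .crank import _KERNELS
from .intensity import IntensityTrace

__all__ = [
    "DeffEstimate",
    "SizeDistribution",
    "RegressionResult",
    "deff_eq1",
    "refine_deff_nm",
    "ensemble_stats",
    "regress_deff_vs_diameter",
    "distribution_weighted_deff",
]


@dataclass
class DeffEstimate:
    track_id: int
    method: str  # "eq1" | "crank_fit" | "eq1_nm_refined"
    deff_m2_s: float
    diameter_m: float
    initial_area_m2: float | None = None
    completion_time_s: float | None = None
    sse: float | None = None
    converged: bool = True


@dataclass
class SizeDistribution:
    """Particle-size distribution as (diameter, volume fraction) bins."""

    bins: list[tuple[float, float]]

    def __post_init__(self) -> None:
        fractions = np.array([f for _, f in self.bins], dtype=float)
        if len(fractions) == 0:
            raise ValueError("empty size distribution")
        if np.any(fractions < 0):
            raise ValueError("volume fractions must be non-negative")
        if abs(fractions.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"volume fractions must sum to 1 (got {fractions.sum():.8f})"
            )

    @classmethod
    def from_csv(cls, path) -> "SizeDistribution":
        df = pd.read_csv(path)
        return cls(bins=list(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class RegressionResult:
    model: str  # "linear" | "quadratic"
    coefficients: np.ndarray  # ascending powers: c0 + c1*d (+ c2*d^2)
    r_squared: float
    diameter_range_m: tuple[float, float] = (0.0, np.inf)

    def predict(self, diameter_m) -> np.ndarray:
        d = np.asarray(diameter_m, dtype=float)
        return np.polynomial.polynomial.polyval(d, self.coefficients)


def deff_eq1(initial_area_m2: float, completion_time_s: float) -> float:
    """Area/time effective diffusivity: initial particle area over the full
    diffusion time.  Both inputs must be positive."""
    if not initial_area_m2 > 0:
        raise ValueError("initial_area_m2 must be positive")
    if not completion_time_s > 0:
        raise ValueError("completion_time_s must be positive")
    return initial_area_m2 / completion_time_s


def refine_deff_nm(
    trace: IntensityTrace,
    radius_m: float,
    d_init_m2_s: float,
    max_iter: int = 500,
    geometry: str = "sphere",
) -> DeffEstimate:
    """Refine an area/time D_eff by Nelder-Mead against the uptake model.

    Minimizes sum_t (I_norm(t) - I_theor(t; D))^2 over D alone, starting at
    ``d_init_m2_s``; the affine baseline/plateau are frozen at the trace's
    first and last observed values.  The search runs on log10(D) so the
    parameter tolerance (1e-3) is relative; objective tolerance 1e-12.
    Non-convergence keeps the initial value and flags the estimate.
    ``geometry`` chooses the uptake kernel ("sphere" = volume average,
    "slice" = equatorial-disc average, matching what a confocal slice sees).
    """
    if not d_init_m2_s > 0:
        raise ValueError("d_init_m2_s must be positive")
    kernel = _KERNELS[geometry]
    times = np.asarray(trace.times_s, dtype=float)
    y = np.asarray(trace.mean_rel_intensity, dtype=float)
    i0, i_inf = float(y[0]), float(y[-1])
    if i_inf <= i0:
        i0, i_inf = min(i0, i_inf), min(i0, i_inf) + 1e-3

    def objective(z: np.ndarray) -> float:
        d = 10.0 ** float(z[0])
        model = i0 + (i_inf - i0) * np.atleast_1d(kernel(d * times / radius_m**2))
        r = y - model
        return float(r @ r)

    res = minimize(
        objective,
        x0=np.array([np.log10(d_init_m2_s)]),
        method="Nelder-Mead",
        options={"xatol": 1e-3 / np.log(10), "fatol": 1e-12, "maxiter": max_iter},
    )
    if res.success:
        deff = 10.0 ** float(res.x[0])
        converged = True
    else:
        deff = d_init_m2_s
        converged = False
    return DeffEstimate(
        track_id=trace.track_id,
        method="eq1_nm_refined",
        deff_m2_s=deff,
        diameter_m=2.0 * radius_m,
        sse=float(res.fun),
        converged=converged,
    )


def ensemble_stats(
    deffs_m2_s, diameters_m, areas_m2=None
) -> dict:
    """Summary statistics of an image set's estimates.

    Returns the arithmetic mean of D, the mean / sample standard deviation
    (n-1) / min / max of the diameters, and (if areas are given) the area
    extremes.  The diameter sd is ``None`` for a single particle.
    """
    d = np.asarray(deffs_m2_s, dtype=float)
    diam = np.asarray(diameters_m, dtype=float)
    if d.size == 0 or diam.size == 0:
        raise ValueError("empty input")
    out = {
        "mean_deff_m2_s": float(d.mean()),
        "mean_diameter_m": float(diam.mean()),
        "sd_diameter_m": float(diam.std(ddof=1)) if diam.size > 1 else None,
        "min_diameter_m": float(diam.min()),
        "max_diameter_m": float(diam.max()),
        "n": int(d.size),
    }
    if areas_m2 is not None:
        a = np.asarray(areas_m2, dtype=float)
        out["min_area_m2"] = float(a.min())
        out["max_area_m2"] = float(a.max())
    return out


def regress_deff_vs_diameter(
    deffs_m2_s, diameters_m, model: str = "linear"
) -> RegressionResult:
    """Ordinary least squares of D_eff on diameter (and diameter^2).

    Requires >= 3 points for linear, >= 4 for quadratic, and non-degenerate
    diameters.  R^2 = 1 - SS_res / SS_tot (0 when D is constant).
    """
    d = np.asarray(deffs_m2_s, dtype=float)
    x = np.asarray(diameters_m, dtype=float)
    degree = {"linear": 1, "quadratic": 2}.get(model)
    if degree is None:
        raise ValueError(f"model must be 'linear' or 'quadratic', got {model!r}")
    if d.size < degree + 2:
        raise ValueError(f"{model} regression needs >= {degree + 2} points, got {d.size}")
    if np.ptp(x) == 0:
        raise ValueError("all diameters identical: regression is degenerate")

    V = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, d, rcond=None)
    pred = V @ coef
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(
        model=model,
        coefficients=coef,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        diameter_range_m=(float(x.min()), float(x.max())),
    )


def distribution_weighted_deff(
    regression: RegressionResult, dist: SizeDistribution
) -> float:
    """Average the fitted D(diameter) model over a size distribution.

    Computes sum_bins fraction * max(0, D_model(diameter)); negative model
    predictions (extrapolation artefacts) are clipped to zero.
    """
    total = 0.0
    for diameter, fraction in dist.bins:
        total += fraction * max(0.0, float(regression.predict(diameter)))
    return total


def estimates_to_frame(estimates: list[DeffEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": e.track_id,
                "method": e.method,
                "deff_m2_s": e.deff_m2_s,
                "diameter_m": e.diameter_m,
                "initial_area_m2": e.initial_area_m2,
                "completion_time_s": e.completion_time_s,
                "converged": e.converged,
            }
            for e in estimates
        ]
    )
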