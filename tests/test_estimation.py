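import numpy as np
import pytest

from powderdiff.crank import CrankFit, predict_trace
from powderdiff.estimation import (
    SizeDistribution, deff_eq1, refine_deff_nm, ensemble_stats,
    regress_deff_vs_diameter, distribution_weighted_deff,
)
from powderdiff.intensity import IntensityTrace
from powderdiff.reference import REFERENCE_PARTICLES, reference_summary


class TestDeffEq1:
    def test_benchmark_particle_arithmetic(self):
        # particle 1's printed area over a 340 s diffusion window
        assert deff_eq1(8.5013e-10, 340.0) == pytest.approx(2.50e-12, rel=1e-3)

    def test_unit_conversion(self):
        assert deff_eq1(1e-12, 1.0) == pytest.approx(1e-12)  # 1 um^2 / 1 s

    def test_equal_numerator_denominator(self):
        assert deff_eq1(123.0, 123.0) == 1.0

    def test_homogeneity(self):
        base = deff_eq1(3e-10, 200.0)
        assert deff_eq1(2 * 3e-10, 200.0) == pytest.approx(2 * base)
        assert deff_eq1(3e-10, 2 * 200.0) == pytest.approx(base / 2)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            deff_eq1(0.0, 10.0)
        with pytest.raises(ValueError):
            deff_eq1(1e-10, 0.0)


def _model_trace(d, radius, i0=0.3, i_inf=0.9, n=80):
    t = np.arange(n) * 3.0
    fit = CrankFit(deff_m2_s=d, radius_m=radius, i0=i0, i_inf=i_inf)
    return IntensityTrace(
        track_id=1, times_s=t, mean_rel_intensity=predict_trace(fit, t)
    )


class TestRefineDeffNM:
    def test_recovery_from_tenfold_start(self):
        d_true, radius = 4e-14, 10e-6
        trace = _model_trace(d_true, radius)
        est = refine_deff_nm(trace, radius, 10 * d_true)
        assert est.converged
        assert est.deff_m2_s == pytest.approx(d_true, rel=0.02)

    def test_fixed_point_at_optimum(self):
        d_true, radius = 4e-14, 10e-6
        trace = _model_trace(d_true, radius)
        est = refine_deff_nm(trace, radius, d_true)
        assert est.deff_m2_s == pytest.approx(d_true, rel=0.01)

    def test_objective_never_worse_than_start(self):
        radius = 8e-6
        rng = np.random.default_rng(5)
        trace = _model_trace(2e-14, radius)
        trace.mean_rel_intensity = np.clip(
            trace.mean_rel_intensity + rng.normal(0, 0.02, trace.times_s.size),
            0, 1,
        )
        d_init = 5e-13
        times, y = trace.times_s, trace.mean_rel_intensity
        i0, i_inf = y[0], y[-1]
        from powderdiff.crank import crank_uptake
        def sse(d):
            m = i0 + (i_inf - i0) * np.atleast_1d(
                crank_uptake(d * times / radius**2))
            return float(((y - m) ** 2).sum())
        est = refine_deff_nm(trace, radius, d_init)
        assert est.sse <= sse(d_init) + 1e-15

    def test_invalid_start_rejected(self):
        with pytest.raises(ValueError):
            refine_deff_nm(_model_trace(1e-14, 1e-5), 1e-5, -1e-14)


class TestEnsembleStats:
    def test_benchmark_table_summaries(self):
        s = reference_summary()
        assert s["mean_deff_m2_s"] == pytest.approx(3.39e-14, abs=0.005e-14)
        assert s["mean_diameter_m"] * 1e6 == pytest.approx(19.2, abs=0.05)
        assert s["sd_diameter_m"] * 1e6 == pytest.approx(11.0, abs=0.05)
        assert s["min_diameter_m"] * 1e6 == pytest.approx(5.37, abs=0.005)
        assert s["max_diameter_m"] * 1e6 == pytest.approx(42.38, abs=0.005)

    def test_single_estimate_has_undefined_sd(self):
        s = ensemble_stats([1e-14], [1e-5])
        assert s["mean_deff_m2_s"] == 1e-14
        assert s["sd_diameter_m"] is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ensemble_stats([], [])


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.array([5.0, 10.0, 20.0, 30.0]) * 1e-6
        d = 2e-9 * x + 1e-15
        r = regress_deff_vs_diameter(d, x, "linear")
        assert r.r_squared == pytest.approx(1.0)
        assert r.coefficients[1] == pytest.approx(2e-9)
        assert r.coefficients[0] == pytest.approx(1e-15)

    def test_benchmark_r2_matches_normal_equations_oracle(self):
        d = np.array([p.deff_m2_s for p in REFERENCE_PARTICLES])
        x = np.array([p.diameter_m for p in REFERENCE_PARTICLES])
        r = regress_deff_vs_diameter(d, x, "linear")
        # independent closed-form OLS via the normal equations
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ d)
        resid = d - X @ beta
        r2 = 1 - resid @ resid / ((d - d.mean()) @ (d - d.mean()))
        assert r.r_squared == pytest.approx(r2, abs=1e-10)
        np.testing.assert_allclose(r.coefficients, beta, rtol=1e-8)

    def test_quadratic_fits_at_least_as_well_as_linear(self):
        d = np.array([p.deff_m2_s for p in REFERENCE_PARTICLES])
        x = np.array([p.diameter_m for p in REFERENCE_PARTICLES])
        lin = regress_deff_vs_diameter(d, x, "linear")
        quad = regress_deff_vs_diameter(d, x, "quadratic")
        assert quad.r_squared >= lin.r_squared

    def test_constant_deff_gives_zero_slope_and_r2(self):
        x = np.array([5.0, 10.0, 20.0]) * 1e-6
        r = regress_deff_vs_diameter(np.full(3, 4e-14), x, "linear")
        assert r.coefficients[1] == pytest.approx(0.0, abs=1e-20)
        assert r.r_squared == 0.0

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            regress_deff_vs_diameter([1e-14, 2e-14], [1e-5, 2e-5], "linear")
        with pytest.raises(ValueError):
            regress_deff_vs_diameter(
                [1e-14, 2e-14, 3e-14], [1e-5, 2e-5, 3e-5], "quadratic"
            )


class TestDistributionWeighting:
    def _linear_reg(self, slope=2e-9, intercept=0.0):
        x = np.array([5e-6, 10e-6, 20e-6, 40e-6])
        return regress_deff_vs_diameter(slope * x + intercept, x, "linear")

    def test_point_mass(self):
        reg = self._linear_reg()
        dist = SizeDistribution(bins=[(15e-6, 1.0)])
        assert distribution_weighted_deff(reg, dist) == pytest.approx(
            float(reg.predict(15e-6))
        )

    def test_two_equal_bins_equal_midpoint_under_linearity(self):
        reg = self._linear_reg()
        dist = SizeDistribution(bins=[(10e-6, 0.5), (30e-6, 0.5)])
        assert distribution_weighted_deff(reg, dist) == pytest.approx(
            float(reg.predict(20e-6))
        )

    def test_negative_predictions_clipped(self):
        reg = self._linear_reg(intercept=-3e-14)  # negative below ~15 um
        dist = SizeDistribution(bins=[(1e-6, 1.0)])
        assert distribution_weighted_deff(reg, dist) == 0.0

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SizeDistribution(bins=[(1e-5, 0.6), (2e-5, 0.6)])
        with pytest.raises(ValueError):
            SizeDistribution(bins=[])
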