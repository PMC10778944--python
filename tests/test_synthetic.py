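import numpy as np
import pytest

from powderdiff.synthetic import (
    SceneConfig, render_series, radial_profile, equatorial_mean_uptake,
)
from oracles import crank_nicolson_sphere


class TestRadialProfile:
    def test_surface_held_at_unity(self):
        for tau in [0.0, 1e-3, 0.1, 2.0]:
            assert radial_profile(1.0, tau) == pytest.approx(1.0, abs=1e-9)

    def test_equilibrium_everywhere(self):
        r = np.linspace(0, 1, 11)
        np.testing.assert_allclose(radial_profile(r, 50.0), 1.0, atol=1e-12)

    def test_monotone_in_tau(self):
        taus = np.logspace(-3, 0.5, 25)
        for r in [0.0, 0.3, 0.7, 0.95]:
            vals = [radial_profile(r, t) for t in taus]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(0.5, -0.1)

    def test_matches_finite_difference_solution(self):
        # mid-sphere concentration vs Crank-Nicolson radial PDE oracle
        profs, _, _ = crank_nicolson_sphere([0.05], n_shells=400, dt=0.05 / 1e4)
        r, u = profs[0]
        assert abs(u[200] - radial_profile(0.5, 0.05)) < 1e-3

    def test_centre_limit_continuous(self):
        # the analytic r->0 limit must agree with nearby radii
        for tau in [0.05, 0.2]:
            assert radial_profile(0.0, tau) == pytest.approx(
                radial_profile(1e-6, tau), abs=1e-6
            )


class TestRenderSeries:
    def test_seed_determinism(self):
        cfg = SceneConfig(image_shape=(128, 128), n_particles=2,
                          radius_range_m=(5e-6, 8e-6), n_frames=5, seed=3)
        s1, _ = render_series(cfg)
        s2, _ = render_series(cfg)
        np.testing.assert_array_equal(s1.stack(), s2.stack())

    def test_background_only_scene(self):
        cfg = SceneConfig(image_shape=(64, 64), n_particles=0, n_frames=3,
                          noise_sd=1.0, seed=0)
        series, truth = render_series(cfg)
        assert truth.particles == []
        assert abs(series.frames[0].mean() - cfg.background_level) < 1.0

    def test_equilibrium_disc_uniform_at_plateau(self):
        # huge D -> last frame interior fully at the plateau level
        cfg = SceneConfig(
            image_shape=(96, 96), n_particles=1, radii_m=(10e-6,),
            deffs_m2_s=(1e-11,), n_frames=10, noise_sd=0.0,
            blur_sigma_px=0.0, seed=2,
        )
        series, truth = render_series(cfg)
        interior = series.frames[-1][truth.particles[0].mask]
        assert np.all(interior == int(cfg.particle_plateau_level))

    def test_ground_truth_pairing_preserved(self):
        radii = (12e-6, 6e-6, 9e-6)
        deffs = (3e-14, 9e-14, 1e-14)
        cfg = SceneConfig(n_particles=3, radii_m=radii, deffs_m2_s=deffs,
                          image_shape=(256, 256), n_frames=2, seed=4)
        _, truth = render_series(cfg)
        got = {(p.radius_m, p.true_deff_m2_s) for p in truth.particles}
        assert got == set(zip(radii, deffs))

    def test_particles_disjoint_and_off_border(self):
        cfg = SceneConfig(seed=6, n_frames=2)
        _, truth = render_series(cfg)
        total = np.zeros(cfg.image_shape, dtype=int)
        for p in truth.particles:
            total += p.mask
        assert total.max() == 1  # no overlap
        assert not total[0].any() and not total[-1].any()
        assert not total[:, 0].any() and not total[:, -1].any()

    def test_impossible_placement_raises(self):
        cfg = SceneConfig(image_shape=(64, 64), n_particles=20,
                          radius_range_m=(8e-6, 9e-6), n_frames=1, seed=0)
        with pytest.raises(ValueError, match="non-overlapping|does not fit"):
            render_series(cfg)

    def test_invalid_levels_rejected(self):
        cfg = SceneConfig(background_level=100, initial_interior_level=50)
        with pytest.raises(ValueError, match="background"):
            cfg.validate()


class TestGeneratorModelConsistency:
    def test_noiseless_interior_mean_matches_slice_average(self):
        """The rendered mean interior intensity, min-max normalized, must
        track the equatorial-slice area-average of the radial profile (the
        generator and the analysis model describe the same physics)."""
        cfg = SceneConfig(
            image_shape=(128, 128), n_particles=1, radii_m=(15e-6,),
            deffs_m2_s=(5e-14,), n_frames=30, noise_sd=0.0,
            blur_sigma_px=0.0, seed=9,
        )
        series, truth = render_series(cfg)
        p = truth.particles[0]
        lo, hi = cfg.initial_interior_level, cfg.particle_plateau_level
        for k in [3, 10, 20, 29]:
            t = series.timestamps_s[k]
            tau = p.true_deff_m2_s * t / p.radius_m**2
            measured = (series.frames[k][p.mask].mean() - lo) / (hi - lo)
            # oracle: direct 2-D summation of the radial profile on the grid
            rows, cols = np.nonzero(p.mask)
            r_rel = np.hypot(rows - p.centre_px[0], cols - p.centre_px[1])
            r_rel /= p.radius_m / cfg.pixel_size_m
            expected = radial_profile(np.clip(r_rel, 0, 1), tau).mean()
            assert measured == pytest.approx(expected, abs=0.02)

    def test_slice_average_differs_from_volume_average(self):
        """Documented discrepancy: an equatorial slice under-weights the
        outer shell, so its average lags the volume uptake at early times."""
        from powderdiff.crank import crank_uptake
        for tau in [0.005, 0.02, 0.1]:
            assert equatorial_mean_uptake(tau) < crank_uptake(tau)
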