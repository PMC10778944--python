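import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from powderdiff.synthetic import SceneConfig, render_series
from oracles import crank_nicolson_sphere


@pytest.fixture(scope="session")
def cn_solution():
    """Finite-difference solution of spherical diffusion on the standard
    tau grid: (taus, volume_uptake, slice_uptake)."""
    taus = np.logspace(-3, 0, 13)
    _, vol, slc = crank_nicolson_sphere(taus, n_shells=400, dt=1e-5)
    return taus, vol, slc


@pytest.fixture(scope="session")
def default_scene():
    """The standard 10-particle, 120-frame synthetic study scene."""
    cfg = SceneConfig(seed=1)
    series, truth = render_series(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noiseless, blur-free scene for exact geometric checks."""
    cfg = SceneConfig(
        image_shape=(256, 256),
        n_particles=4,
        radius_range_m=(5e-6, 15e-6),
        n_frames=40,
        noise_sd=0.0,
        blur_sigma_px=0.0,
        seed=11,
    )
    series, truth = render_series(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def monotone_scene_results():
    """Completion times from a scene of equal-radius particles whose true D
    spans a log grid: list of (true_D, completion_time_s) sorted by D."""
    from powderdiff.pipeline import RunConfig, run_pipeline

    ds = np.logspace(-14, -13, 6)
    cfg = SceneConfig(
        n_particles=6, radii_m=tuple([10e-6] * 6), deffs_m2_s=tuple(ds), seed=7
    )
    res = run_pipeline(RunConfig(scene=cfg, mode="ml", seed=7))
    rows = []
    for e in res.ml_estimates:
        if e.method != "eq1":
            continue
        track = next(t for t in res.tracks if t.track_id == e.track_id)
        p = match_truth(track, res.ground_truth)
        rows.append((p.true_deff_m2_s, e.completion_time_s))
    return sorted(rows)


def match_truth(track, truth):
    """Ground-truth particle nearest to a track's first centroid."""
    c = track.first_region.centroid_px
    return min(
        truth.particles,
        key=lambda p: (p.centre_px[0] - c[0]) ** 2 + (p.centre_px[1] - c[1]) ** 2,
    )
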