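"""End-to-end orchestration of the two analysis pathways.

``matlab`` pathway: segment -> track -> bbox intensity trace -> least-squares
Crank fit per particle.

``ml`` pathway: masks (built-in segmenter or imported COCO annotations) ->
track -> mask intensity trace (q1, std_norm) -> rule-based endpoint ->
area/time estimate -> Nelder-Mead refinement.

``run_pipeline`` is deterministic given the configuration (including the
synthetic-scene seed), persists every stage's table into the output
directory, and records particles that fail a stage with the failing stage
rather than dropping them silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .segmentation import (
    DEFAULT_MIN_AREA_PX, segment_series, regions_from_masks, regions_to_frame,
)
from .tracking import DEFAULT_MAX_DISPLACEMENT_PX, build_tracks, tracks_to_frame
from .intensity import DEFAULT_Q1_QUANTILE, trace_for_track, traces_to_frame
from .endpoint import RuleConstants, detect_completion, decisions_to_frame
from .crank import fit_deff
from .estimation import (
    DeffEstimate, SizeDistribution, deff_eq1, refine_deff_nm, ensemble_stats,
    regress_deff_vs_diameter, distribution_weighted_deff, estimates_to_frame,
)
from .synthetic import SceneConfig, render_series

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (serialized into the output)."""

    # input: either a path to images ...
    input_path: str | None = None
    pixel_size_m: float = 440e-9
    frame_interval_s: float | None = 3.0
    timestamps_s: list[float] | None = None
    t_offset_s: float = 0.0
    channel: str = "green"
    coco_masks_path: str | None = None
    # ... or a synthetic scene
    scene: SceneConfig | None = None

    mode: str = "both"  # "matlab" | "ml" | "both"
    # image-derived traces average over the confocal slice, so the slice
    # kernel is the default for fitting; "sphere" = raw volume uptake
    fit_geometry: str = "slice"
    min_area_px: int = DEFAULT_MIN_AREA_PX
    max_displacement_px: float = DEFAULT_MAX_DISPLACEMENT_PX
    q1_quantile: float = DEFAULT_Q1_QUANTILE
    endpoint_constants: RuleConstants = field(default_factory=RuleConstants)
    size_distribution_path: str | None = None
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.scene is None):
            raise ValueError("exactly one of input_path / scene must be given")
        if self.mode not in ("matlab", "ml", "both"):
            raise ValueError(f"mode must be matlab|ml|both, got {self.mode!r}")
        if self.scene is not None and self.scene.n_frames < 1:
            raise ValueError("scene must have at least one frame")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    series: "pio.FrameSeries"
    regions_per_frame: list
    tracks: list
    matlab_estimates: list[DeffEstimate]
    ml_estimates: list[DeffEstimate]
    failures: list[dict]
    summary: dict
    ground_truth: object | None = None


def _summarize(estimates: list[DeffEstimate]) -> dict:
    ok = [e for e in estimates if e.converged and e.deff_m2_s > 0]
    if not ok:
        return {"n": 0}
    deffs = [e.deff_m2_s for e in ok]
    diams = [e.diameter_m for e in ok]
    out = ensemble_stats(deffs, diams)
    if len(ok) >= 3 and np.ptp(diams) > 0:
        lin = regress_deff_vs_diameter(deffs, diams, "linear")
        out["regression_linear"] = {
            "coefficients": lin.coefficients.tolist(),
            "r_squared": lin.r_squared,
        }
        if len(ok) >= 4:
            quad = regress_deff_vs_diameter(deffs, diams, "quadratic")
            out["regression_quadratic"] = {
                "coefficients": quad.coefficients.tolist(),
                "r_squared": quad.r_squared,
            }
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the configured pathway(s) and return (and optionally persist)
    every stage's output."""
    config.validate()
    truth = None
    if config.scene is not None:
        series, truth = render_series(config.scene)
    else:
        series = pio.read_series(
            config.input_path,
            pixel_size_m=config.pixel_size_m,
            frame_interval_s=config.frame_interval_s,
            timestamps_s=config.timestamps_s,
            t_offset_s=config.t_offset_s,
            channel=config.channel,
        )

    if config.coco_masks_path is not None:
        masks = pio.import_coco_masks(config.coco_masks_path, series)
        regions_per_frame = regions_from_masks(
            masks, series.pixel_size_m, config.min_area_px
        )
    else:
        regions_per_frame = segment_series(series, config.min_area_px)

    tracks = build_tracks(regions_per_frame, config.max_displacement_px)
    complete = [t for t in tracks if t.complete]
    failures: list[dict] = [
        {"track_id": t.track_id, "stage": "tracking",
         "reason": "appeared after first frame (incomplete track)"}
        for t in tracks if not t.complete
    ]

    matlab_estimates: list[DeffEstimate] = []
    ml_estimates: list[DeffEstimate] = []
    matlab_traces, ml_traces, decisions = [], [], []

    if config.mode in ("matlab", "both"):
        for tr in complete:
            try:
                trace = trace_for_track(tr, series, mode="matlab")
                fit = fit_deff(trace, tr.first_region.radius_m,
                               geometry=config.fit_geometry)
                matlab_traces.append(trace)
                matlab_estimates.append(
                    DeffEstimate(
                        track_id=tr.track_id,
                        method="crank_fit",
                        deff_m2_s=fit.deff_m2_s,
                        diameter_m=tr.first_region.equivalent_diameter_m,
                        initial_area_m2=tr.first_region.area_m2,
                        sse=fit.sse,
                        converged=fit.converged,
                    )
                )
            except ValueError as exc:
                failures.append(
                    {"track_id": tr.track_id, "stage": "crank_fit", "reason": str(exc)}
                )

    if config.mode in ("ml", "both"):
        for tr in complete:
            try:
                trace = trace_for_track(
                    tr, series, mode="ml", q1_quantile=config.q1_quantile
                )
                ml_traces.append(trace)
                decision = detect_completion(trace, config.endpoint_constants)
                decisions.append(decision)
                if not decision.completed:
                    failures.append(
                        {"track_id": tr.track_id, "stage": "endpoint",
                         "reason": "no completion criterion fired"}
                    )
                    continue
                t_full = decision.completion_time_s + series.t_offset_s
                if t_full <= 0:
                    failures.append(
                        {"track_id": tr.track_id, "stage": "eq1",
                         "reason": "completion at t=0: area/time undefined"}
                    )
                    continue
                d0 = deff_eq1(tr.first_region.area_m2, t_full)
                ml_estimates.append(
                    DeffEstimate(
                        track_id=tr.track_id,
                        method="eq1",
                        deff_m2_s=d0,
                        diameter_m=tr.first_region.equivalent_diameter_m,
                        initial_area_m2=tr.first_region.area_m2,
                        completion_time_s=t_full,
                    )
                )
                refined = refine_deff_nm(trace, tr.first_region.radius_m, d0,
                                         geometry=config.fit_geometry)
                refined.initial_area_m2 = tr.first_region.area_m2
                refined.completion_time_s = t_full
                ml_estimates.append(refined)
            except ValueError as exc:
                failures.append(
                    {"track_id": tr.track_id, "stage": "ml_pathway", "reason": str(exc)}
                )

    summary = {
        "n_frames": series.n_frames,
        "n_regions_first_frame": len(regions_per_frame[0]) if regions_per_frame else 0,
        "n_tracks": len(tracks),
        "n_complete_tracks": len(complete),
        "matlab": _summarize([e for e in matlab_estimates if e.method == "crank_fit"]),
        "ml_eq1": _summarize([e for e in ml_estimates if e.method == "eq1"]),
        "ml_refined": _summarize(
            [e for e in ml_estimates if e.method == "eq1_nm_refined"]
        ),
    }

    if config.size_distribution_path is not None:
        dist = SizeDistribution.from_csv(config.size_distribution_path)
        for key, ests in (
            ("matlab", [e for e in matlab_estimates if e.method == "crank_fit"]),
            ("ml_eq1", [e for e in ml_estimates if e.method == "eq1"]),
        ):
            good = [e for e in ests if e.converged]
            if len(good) >= 3:
                reg = regress_deff_vs_diameter(
                    [e.deff_m2_s for e in good], [e.diameter_m for e in good], "linear"
                )
                summary[key]["distribution_weighted_deff_m2_s"] = (
                    distribution_weighted_deff(reg, dist)
                )

    result = PipelineResult(
        series=series,
        regions_per_frame=regions_per_frame,
        tracks=tracks,
        matlab_estimates=matlab_estimates,
        ml_estimates=ml_estimates,
        failures=failures,
        summary=summary,
        ground_truth=truth,
    )

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = config.to_dict()
        cfg["endpoint_constants"] = asdict(config.endpoint_constants)
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
        regions_to_frame(regions_per_frame).to_csv(outdir / "regions.csv", index=False)
        tracks_to_frame(tracks).to_csv(outdir / "tracks.csv", index=False)
        if matlab_traces:
            traces_to_frame(matlab_traces).to_csv(
                outdir / "traces_matlab.csv", index=False
            )
        if ml_traces:
            traces_to_frame(ml_traces).to_csv(outdir / "traces_ml.csv", index=False)
        if decisions:
            decisions_to_frame(decisions).to_csv(outdir / "endpoints.csv", index=False)
        estimates_to_frame(matlab_estimates + ml_estimates).to_csv(
            outdir / "estimates.csv", index=False
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        if failures:
            with open(outdir / "failures.json", "w") as fh:
                json.dump(failures, fh, indent=2)
    return result
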