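"""Per-track fluorescence-intensity time series.

The dye concentration inside a particle is read out through min-max
normalized fluorescence: Int_rel = (Int - Int_min) / (Int_max - Int_min).
Two measurement conventions are supported, matching the two analysis
pathways:

``matlab`` mode
    Pixels inside the particle's first-frame bounding box; Int_min / Int_max
    are the extreme pixel intensities observed in that box over the whole
    series.  Output: the mean relative intensity per frame (the quantity the
    Crank model is fitted to).

``ml`` mode
    Pixels inside the particle's first-frame mask; Int_min is the minimum
    pixel intensity anywhere in the initial micrograph, Int_max = 255
    (the 8-bit ceiling).  Outputs additionally q1 (a low quantile of the raw
    pixel intensities, default the first quartile) and the standard deviation
    of the normalized pixel intensities — the inputs of the rule-based
    diffusion-endpoint detector.

Masks and boxes are taken from the first observation and held static
(particle motion is negligible); per-frame domains can be enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FrameSeries
from .tracking import ParticleTrack

__all__ = ["IntensityTrace", "relative_intensity", "trace_for_track", "traces_to_frame"]

DEFAULT_Q1_QUANTILE = 0.25


@dataclass
class IntensityTrace:
    """Intensity time series of one tracked particle."""

    track_id: int
    times_s: np.ndarray
    mean_rel_intensity: np.ndarray
    q1: np.ndarray | None = None
    std_norm: np.ndarray | None = None
    int_min: float = 0.0
    int_max: float = 255.0
    measurement_domain: str = "mask"  # "mask" or "bbox"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.mean_rel_intensity = np.asarray(self.mean_rel_intensity, dtype=float)
        n = len(self.times_s)
        for name in ("mean_rel_intensity", "q1", "std_norm"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length {len(v)} != {n} time points")


def relative_intensity(int_value, int_min: float, int_max: float):
    """Min-max normalized intensity, clipped to [0, 1].

    Raises if ``int_max <= int_min`` (degenerate normalization).
    """
    if int_max <= int_min:
        raise ValueError(
            f"degenerate normalization: int_max ({int_max}) <= int_min ({int_min})"
        )
    return np.clip((np.asarray(int_value, dtype=float) - int_min)
                   / (int_max - int_min), 0.0, 1.0)


def trace_for_track(
    track: ParticleTrack,
    series: FrameSeries,
    mode: str = "matlab",
    q1_quantile: float = DEFAULT_Q1_QUANTILE,
    static_domain: bool = True,
) -> IntensityTrace:
    """Measure a particle's intensity trace in the requested convention."""
    if mode not in ("matlab", "ml"):
        raise ValueError(f"mode must be 'matlab' or 'ml', got {mode!r}")
    if track.n_obs == 0:
        raise ValueError(f"track {track.track_id} has no observations")

    frame_idx = track.frame_indices
    times = series.timestamps_s[frame_idx]
    first = track.first_region

    def domain_pixels(obs_i: int) -> np.ndarray:
        region = first if static_domain else track.observations[obs_i][1]
        frame = series.frames[track.observations[obs_i][0]]
        if mode == "matlab":
            r0, c0, h, w = region.bbox
            px = frame[r0:r0 + h, c0:c0 + w].ravel()
        else:
            px = frame[region.mask]
        if px.size == 0:
            raise ValueError(f"track {track.track_id}: empty measurement domain")
        return px.astype(float)

    all_px = [domain_pixels(i) for i in range(track.n_obs)]

    if mode == "matlab":
        int_min = min(float(px.min()) for px in all_px)
        int_max = max(float(px.max()) for px in all_px)
        mean_rel = relative_intensity(
            np.array([px.mean() for px in all_px]), int_min, int_max
        )
        return IntensityTrace(
            track_id=track.track_id,
            times_s=times,
            mean_rel_intensity=mean_rel,
            int_min=int_min,
            int_max=int_max,
            measurement_domain="bbox",
        )

    # minimum over the whole initial micrograph (not just the particle):
    # keeps the normalization well defined even for a uniformly bright mask
    int_min = float(series.frames[track.observations[0][0]].min())
    int_max = 255.0
    mean_rel = relative_intensity(
        np.array([px.mean() for px in all_px]), int_min, int_max
    )
    q1 = np.array([np.quantile(px, q1_quantile) for px in all_px])
    std_norm = np.array(
        [np.std(relative_intensity(px, int_min, int_max)) for px in all_px]
    )
    return IntensityTrace(
        track_id=track.track_id,
        times_s=times,
        mean_rel_intensity=mean_rel,
        q1=q1,
        std_norm=std_norm,
        int_min=int_min,
        int_max=int_max,
        measurement_domain="mask",
    )


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for k in range(len(tr.times_s)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "time_s": tr.times_s[k],
                    "mean_rel_intensity": tr.mean_rel_intensity[k],
                    "q1": tr.q1[k] if tr.q1 is not None else np.nan,
                    "std_norm": tr.std_norm[k] if tr.std_norm is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
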