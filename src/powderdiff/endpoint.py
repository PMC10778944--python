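"""Rule-based detection of the moment a particle finishes hydrating.

Operating on the ml-mode intensity trace (q1 = low quantile of raw pixel
intensities, std_norm = standard deviation of normalized pixel intensities),
three empirical criteria are scanned frame by frame; the earliest firing
frame marks diffusion completion:

I.   the change of q1's rate of change between consecutive micrographs (the
     discrete second difference) drops below -4.99 while q1 exceeds 80
     (~31% of the 8-bit ceiling) — the q1 curve has hit its shoulder;
II.  q1 exceeds 100 (40% of the ceiling) — the particle interior is bright;
III. std_norm changes by less than 1e-4 between frames, std_norm is below
     0.18 and q1 exceeds 80 — the intensity field has become flat and static.

All comparisons are strict.  If several criteria fire at the same frame the
priority is I > II > III; if none fires the particle is reported as not
completed.  The constants are configuration with the empirical defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intensity import IntensityTrace

__all__ = ["RuleConstants", "EndpointDecision", "detect_completion", "decisions_to_frame"]


@dataclass(frozen=True)
class RuleConstants:
    q1_accel_drop: float = -4.99  # criterion I: second difference of q1 below this
    q1_shoulder: float = 80.0     # criteria I and III: q1 must exceed this
    q1_bright: float = 100.0      # criterion II: q1 must exceed this
    std_change: float = 0.0001    # criterion III: |delta std_norm| below this
    std_level: float = 0.18       # criterion III: std_norm below this


@dataclass
class EndpointDecision:
    """Outcome of endpoint detection for one track."""

    track_id: int
    completed: bool
    completion_time_s: float | None
    criterion: str  # "I" | "II" | "III" | "none"
    frame_of_completion: int | None = None
    dq1: np.ndarray | None = None       # first difference of q1
    ddq1: np.ndarray | None = None      # second difference of q1
    dstd: np.ndarray | None = None      # first difference of std_norm


def detect_completion(
    trace: IntensityTrace, constants: RuleConstants = RuleConstants()
) -> EndpointDecision:
    """Scan a trace in time order and return the earliest-firing criterion.

    Requires an ml-mode trace (q1 and std_norm populated) with >= 3 points.
    Criterion II can fire at any frame k >= 0; III needs k >= 1 (a previous
    std_norm value); I needs k >= 2 (two consecutive rate changes).
    """
    if trace.q1 is None or trace.std_norm is None:
        raise ValueError(
            f"track {trace.track_id}: trace lacks q1/std_norm — "
            "endpoint detection needs an ml-mode trace"
        )
    q1 = np.asarray(trace.q1, dtype=float)
    std = np.asarray(trace.std_norm, dtype=float)
    if len(q1) < 3:
        raise ValueError(f"track {trace.track_id}: need >= 3 points, got {len(q1)}")

    dq1 = np.diff(q1)          # dq1[k-1] = q1[k] - q1[k-1]
    ddq1 = np.diff(dq1)        # ddq1[k-2] = dq1[k-1] - dq1[k-2]
    dstd = np.diff(std)

    c = constants
    for k in range(len(q1)):
        fired = None
        if k >= 2 and ddq1[k - 2] < c.q1_accel_drop and q1[k] > c.q1_shoulder:
            fired = "I"
        elif q1[k] > c.q1_bright:
            fired = "II"
        elif (k >= 1 and abs(dstd[k - 1]) < c.std_change
              and std[k] < c.std_level and q1[k] > c.q1_shoulder):
            fired = "III"
        if fired is not None:
            return EndpointDecision(
                track_id=trace.track_id,
                completed=True,
                completion_time_s=float(trace.times_s[k]),
                criterion=fired,
                frame_of_completion=k,
                dq1=dq1, ddq1=ddq1, dstd=dstd,
            )
    return EndpointDecision(
        track_id=trace.track_id,
        completed=False,
        completion_time_s=None,
        criterion="none",
        dq1=dq1, ddq1=ddq1, dstd=dstd,
    )


def decisions_to_frame(decisions: list[EndpointDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": d.track_id,
                "completed": d.completed,
                "completion_time_s": d.completion_time_s,
                "criterion": d.criterion,
            }
            for d in decisions
        ]
    )
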