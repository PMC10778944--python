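"""Nearest-neighbour particle tracking across frames.

Particles in the rehydration experiment are effectively static (movement in
the dispersion is negligible on the acquisition timescale), so linking is
done greedily: candidate pairs between adjacent frames are sorted by
Euclidean distance in the 4-D bounding-box feature space (corner row, corner
col, width, height) and accepted one-to-one in that order, gated by a maximum
centroid displacement.  For well-separated static particles this coincides
with the globally optimal assignment (asserted against brute force in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import ParticleRegion

__all__ = ["ParticleTrack", "match_frames", "build_tracks", "tracks_to_frame"]

DEFAULT_MAX_DISPLACEMENT_PX = 15.0


@dataclass
class ParticleTrack:
    """One physical particle followed through frames.

    ``complete`` is True only if the track starts in the first frame, i.e.
    the particle's initial area (the quantity entering the area/time estimate)
    was observed.
    """

    track_id: int
    observations: list[tuple[int, ParticleRegion]] = field(default_factory=list)
    complete: bool = True

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def first_region(self) -> ParticleRegion:
        return self.observations[0][1]

    @property
    def frame_indices(self) -> list[int]:
        return [f for f, _ in self.observations]


def match_frames(
    regions_a: list[ParticleRegion],
    regions_b: list[ParticleRegion],
    max_displacement_px: float = DEFAULT_MAX_DISPLACEMENT_PX,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of regions in two adjacent frames.

    All (a, b) candidate pairs are ranked by Euclidean distance between their
    bounding-box feature vectors; pairs are accepted in that order when
    neither member is already matched and the centroid displacement does not
    exceed ``max_displacement_px``.  Distance ties break toward smaller
    labels (a first, then b).  Returns index pairs into the two input lists.
    """
    if not regions_a or not regions_b:
        return []
    fa = np.stack([r.bbox_feature for r in regions_a])
    fb = np.stack([r.bbox_feature for r in regions_b])
    ca = np.array([r.centroid_px for r in regions_a])
    cb = np.array([r.centroid_px for r in regions_b])

    dist = np.linalg.norm(fa[:, None, :] - fb[None, :, :], axis=2)
    disp = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)

    candidates = [
        (dist[i, j], regions_a[i].label, regions_b[j].label, i, j)
        for i in range(len(regions_a))
        for j in range(len(regions_b))
        if disp[i, j] <= max_displacement_px
    ]
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


def build_tracks(
    series_regions: list[list[ParticleRegion]],
    max_displacement_px: float = DEFAULT_MAX_DISPLACEMENT_PX,
) -> list[ParticleTrack]:
    """Chain adjacent-frame matches into per-particle tracks.

    No gap closing: a region unmatched in the next frame terminates its
    track, and a region appearing after frame 0 starts a new track flagged
    not-complete.  Track ids are assigned by first appearance (frame, label).
    """
    if not series_regions:
        return []
    tracks: list[ParticleTrack] = []
    # open_tracks[i] = track currently ending at region index i of the latest frame
    open_tracks: dict[int, ParticleTrack] = {}
    for i, region in enumerate(series_regions[0]):
        tr = ParticleTrack(track_id=0, complete=True)
        tr.observations.append((0, region))
        tracks.append(tr)
        open_tracks[i] = tr

    for f in range(1, len(series_regions)):
        prev, cur = series_regions[f - 1], series_regions[f]
        pairs = match_frames(prev, cur, max_displacement_px)
        matched_b = {j for _, j in pairs}
        next_open: dict[int, ParticleTrack] = {}
        for i, j in pairs:
            tr = open_tracks.get(i)
            if tr is None:  # previous region had no track (should not happen)
                continue
            tr.observations.append((f, cur[j]))
            next_open[j] = tr
        for j, region in enumerate(cur):
            if j not in matched_b:
                tr = ParticleTrack(track_id=0, complete=False)
                tr.observations.append((f, region))
                tracks.append(tr)
                next_open[j] = tr
        open_tracks = next_open

    tracks.sort(key=lambda t: (t.observations[0][0], t.observations[0][1].label))
    for k, tr in enumerate(tracks):
        tr.track_id = k + 1
    return tracks


def tracks_to_frame(tracks: list[ParticleTrack]) -> pd.DataFrame:
    rows = [
        {
            "track_id": t.track_id,
            "frame": f,
            "label": r.label,
            "complete": t.complete,
        }
        for t in tracks
        for f, r in t.observations
    ]
    return pd.DataFrame(rows)
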