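"""Frame binarization, particle labeling and per-particle morphology.

Each micrograph is thresholded with Otsu's method (foreground = pixels
strictly above the threshold), background holes inside particles are filled,
8-connected components are labeled, and small or border-touching components
are discarded.  For each surviving region the area, equivalent diameter,
centroid and bounding box are computed — the geometric inputs of the
diffusion models (the equivalent radius plays the role of the sphere radius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "ParticleRegion",
    "otsu_threshold",
    "segment_frame",
    "segment_series",
    "regions_from_masks",
    "equivalent_diameter",
    "regions_to_frame",
]

DEFAULT_MIN_AREA_PX = 20


@dataclass
class ParticleRegion:
    """One segmented particle in one frame.

    ``bbox`` follows the package convention (row_min, col_min, height, width),
    half-open; ``equivalent_diameter_m`` is the diameter of the circle with
    the same area, 2*sqrt(A/pi).
    """

    label: int
    frame_index: int
    mask: np.ndarray  # full-frame boolean mask
    area_px: int
    area_m2: float
    equivalent_diameter_m: float
    centroid_px: tuple[float, float]
    bbox: tuple[int, int, int, int]

    @property
    def radius_m(self) -> float:
        return self.equivalent_diameter_m / 2.0

    @property
    def bbox_feature(self) -> np.ndarray:
        """(corner row, corner col, width, height) — the tracking features."""
        r0, c0, h, w = self.bbox
        return np.array([r0, c0, w, h], dtype=float)


def otsu_threshold(histogram) -> int:
    """Otsu's threshold from a 256-bin intensity histogram.

    Returns the intensity T (0-255) maximizing the between-class variance of
    the split {<= T} vs {> T}; foreground is defined as pixels strictly
    greater than T.  Ties are broken toward the smallest maximizing T.

    Raises
    ------
    ValueError
        If fewer than two histogram bins are occupied (no separable classes).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise ValueError("image has a single intensity value: no separable classes")

    levels = np.arange(256, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist)  # weight of class {<= T}
    m0 = np.cumsum(hist * levels)  # unnormalized class-0 mean
    mu_total = m0[-1]
    w1 = total - w0
    # between-class variance for every candidate T; invalid where a class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximum


def equivalent_diameter(area_m2: float) -> float:
    """Diameter of the circle with the given area: 2*sqrt(A/pi)."""
    if not area_m2 > 0:
        raise ValueError("area must be positive")
    return 2.0 * np.sqrt(area_m2 / np.pi)


def _region_from_mask(
    mask: np.ndarray, label: int, frame_index: int, pixel_size_m: float
) -> ParticleRegion:
    rows, cols = np.nonzero(mask)
    area_px = rows.size
    area_m2 = area_px * pixel_size_m**2
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    return ParticleRegion(
        label=label,
        frame_index=frame_index,
        mask=mask,
        area_px=int(area_px),
        area_m2=float(area_m2),
        equivalent_diameter_m=equivalent_diameter(area_m2),
        centroid_px=(float(rows.mean()), float(cols.mean())),
        bbox=(r0, c0, r1 - r0 + 1, c1 - c0 + 1),
    )


def segment_frame(
    frame: np.ndarray,
    pixel_size_m: float,
    frame_index: int = 0,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    discard_border: bool = True,
) -> list[ParticleRegion]:
    """Segment one frame into particle regions.

    Pipeline: Otsu binarization -> hole filling -> 8-connected labeling ->
    discard regions smaller than ``min_area_px`` or touching the image border
    (their geometry is truncated) -> morphology per surviving region.
    Labels are reassigned 1..K in decreasing area order.

    A frame with a single intensity value yields zero regions (no separable
    classes is treated as "nothing to segment").
    """
    frame = np.asarray(frame)
    hist = np.bincount(frame.ravel(), minlength=256)[:256]
    try:
        thr = otsu_threshold(hist)
    except ValueError:
        return []
    binary = frame > thr
    filled = ndimage.binary_fill_holes(binary)
    labels = measure.label(filled, connectivity=2)

    regions: list[ParticleRegion] = []
    h, w = frame.shape
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() < min_area_px:
            continue
        if discard_border:
            rows, cols = np.nonzero(mask)
            if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
                continue
        regions.append(_region_from_mask(mask, 0, frame_index, pixel_size_m))
    regions.sort(key=lambda r: -r.area_px)
    for i, r in enumerate(regions):
        r.label = i + 1
    return regions


def segment_series(series, min_area_px: int = DEFAULT_MIN_AREA_PX,
                   discard_border: bool = True) -> list[list[ParticleRegion]]:
    """Segment every frame of a series (per-frame Otsu threshold)."""
    return [
        segment_frame(f, series.pixel_size_m, i, min_area_px, discard_border)
        for i, f in enumerate(series.frames)
    ]


def regions_from_masks(
    masks_per_frame: list[list[np.ndarray]],
    pixel_size_m: float,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> list[list[ParticleRegion]]:
    """Build regions from externally supplied instance masks (e.g. COCO import).

    Masks are used as given (no thresholding); holes are filled and the small-
    area filter applied so downstream contracts match the built-in segmenter.
    """
    out: list[list[ParticleRegion]] = []
    for frame_index, masks in enumerate(masks_per_frame):
        regions = []
        for m in masks:
            filled = ndimage.binary_fill_holes(np.asarray(m, dtype=bool))
            if filled.sum() < min_area_px:
                continue
            regions.append(_region_from_mask(filled, 0, frame_index, pixel_size_m))
        regions.sort(key=lambda r: -r.area_px)
        for i, r in enumerate(regions):
            r.label = i + 1
        out.append(regions)
    return out


def regions_to_frame(regions_per_frame: list[list[ParticleRegion]]) -> pd.DataFrame:
    """Flatten per-frame region lists into a tidy table."""
    rows = []
    for regions in regions_per_frame:
        for r in regions:
            rows.append(
                {
                    "frame": r.frame_index,
                    "label": r.label,
                    "area_px": r.area_px,
                    "area_m2": r.area_m2,
                    "equivalent_diameter_m": r.equivalent_diameter_m,
                    "centroid_row": r.centroid_px[0],
                    "centroid_col": r.centroid_px[1],
                    "bbox_row": r.bbox[0],
                    "bbox_col": r.bbox[1],
                    "bbox_height": r.bbox[2],
                    "bbox_width": r.bbox[3],
                }
            )
    return pd.DataFrame(rows)
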