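"""Reading and writing time-lapse greyscale image series with physical metadata.

The experimental input is a time-ordered stack of 8-bit confocal micrographs
(typically 512 x 512 px at 440 nm/px, ~3 s frame spacing) showing fluorescent
dye penetrating powder particles.  This module provides the in-memory
container (:class:`FrameSeries`), readers for multi-page TIFF stacks and
directories of numbered TIFF/PNG frames, and an importer for externally
produced instance masks in COCO annotation JSON.

Coordinate convention throughout the package: row-major, 0-based pixel
indices; bounding boxes are ``(row_min, col_min, height, width)``, half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile
import yaml
import shapely

__all__ = [
    "FrameSeries",
    "read_series",
    "write_series",
    "import_coco_masks",
    "read_metadata_sidecar",
]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass
class FrameSeries:
    """A time-lapse greyscale image series with physical calibration.

    Parameters
    ----------
    frames : list of 2-D uint8 arrays
        Intensity images in acquisition order, identical shapes, values 0-255.
    timestamps_s : array of float
        Seconds since the first frame; strictly increasing, one per frame.
    pixel_size_m : float
        Physical size of one pixel in metres (> 0).
    t_offset_s : float
        Time elapsed before the first frame (e.g. delay between dye addition
        and the first capture).  Kept separate so model fitting uses the
        in-series clock while reports can quote absolute time.
    name : str
        Free-text identifier.
    """

    frames: list[np.ndarray]
    timestamps_s: np.ndarray
    pixel_size_m: float
    t_offset_s: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f) for f in self.frames]
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if len(self.frames) == 0:
            raise ValueError("FrameSeries requires at least one frame")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D (shape {f.shape})")
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} shape {f.shape} differs from frame 0 shape {shape}"
                )
            if f.dtype != np.uint8:
                if np.issubdtype(f.dtype, np.integer) and f.min() >= 0 and f.max() <= 255:
                    self.frames[i] = f.astype(np.uint8)
                else:
                    raise ValueError(
                        f"frame {i}: intensities must be integers in [0, 255] "
                        f"(dtype {f.dtype})"
                    )
        if len(self.timestamps_s) != len(self.frames):
            raise ValueError(
                f"{len(self.timestamps_s)} timestamps for {len(self.frames)} frames"
            )
        if len(self.timestamps_s) > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.pixel_size_m > 0:
            raise ValueError("pixel_size_m must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def stack(self) -> np.ndarray:
        """All frames as a single (n_frames, H, W) uint8 array."""
        return np.stack(self.frames)


def _load_page(path: Path, channel: str) -> np.ndarray:
    """Load one image file as a 2-D uint8 array, reducing colour if needed."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 2:  # grey + alpha
            arr = arr[:, :, 0]
        else:
            try:
                arr = arr[:, :, _CHANNEL_INDEX[channel]]
            except KeyError:
                raise ValueError(f"unknown channel {channel!r}") from None
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path}: unsupported bit depth {arr.dtype}; only 8-bit images are accepted"
        )
    return arr


def read_series(
    path: str | Path,
    pixel_size_m: float,
    frame_interval_s: float | None = None,
    timestamps_s: Sequence[float] | None = None,
    t_offset_s: float = 0.0,
    channel: str = "green",
) -> FrameSeries:
    """Read a time-lapse series from a multi-page TIFF or a directory of frames.

    ``path`` may be a multi-page (or single-page) TIFF file, a single PNG, or
    a directory whose TIFF/PNG files are taken in lexicographic order.  Either
    ``frame_interval_s`` (timestamps generated as ``i * interval``) or an
    explicit ``timestamps_s`` list must be given.  Colour images are reduced
    to one channel (default green, matching pseudo-coloured confocal output);
    images deeper than 8 bits are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")

    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG files found in {path}")
        for f in files:
            page = _load_page(f, channel)
            if frames and page.shape != frames[0].shape:
                raise ValueError(
                    f"{f}: shape {page.shape} differs from first frame "
                    f"shape {frames[0].shape}"
                )
            frames.append(page)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                arr = page.asarray()
                if arr.ndim == 3:
                    arr = arr[:, :, _CHANNEL_INDEX.get(channel, 1)]
                if arr.dtype != np.uint8:
                    raise ValueError(
                        f"{path} page {i}: unsupported bit depth {arr.dtype}; "
                        "only 8-bit images are accepted"
                    )
                if frames and arr.shape != frames[0].shape:
                    raise ValueError(
                        f"{path} page {i}: shape {arr.shape} differs from "
                        f"page 0 shape {frames[0].shape}"
                    )
                frames.append(arr)
    else:
        frames.append(_load_page(path, channel))

    if timestamps_s is not None:
        ts = np.asarray(timestamps_s, dtype=float)
    elif frame_interval_s is not None:
        ts = np.arange(len(frames), dtype=float) * float(frame_interval_s)
    else:
        raise ValueError("either frame_interval_s or timestamps_s is required")

    return FrameSeries(
        frames=frames,
        timestamps_s=ts,
        pixel_size_m=float(pixel_size_m),
        t_offset_s=float(t_offset_s),
        name=path.name,
    )


def write_series(series: FrameSeries, path: str | Path) -> None:
    """Write a series as a multi-page 8-bit TIFF (round-trips bit-exactly)."""
    tifffile.imwrite(Path(path), series.stack(), photometric="minisblack")


def read_metadata_sidecar(path: str | Path) -> dict:
    """Read acquisition metadata (pixel_size_m, frame_interval_s, t_offset_s)
    from a YAML or JSON sidecar file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# COCO instance-annotation import
# ---------------------------------------------------------------------------

def _decode_rle(counts: Sequence[int], height: int, width: int) -> np.ndarray:
    """Decode uncompressed COCO RLE (column-major, starting with background)."""
    flat = np.zeros(height * width, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        flat[pos:pos + c] = val
        pos += c
        val = not val
    if pos != height * width:
        raise ValueError(
            f"RLE counts sum to {pos}, expected {height * width}"
        )
    return flat.reshape((width, height)).T  # column-major


def _rasterize_polygon(coords: Sequence[float], height: int, width: int) -> np.ndarray:
    """Rasterize one COCO polygon: pixel centres inside or on the boundary.

    COCO polygons are flat [x0, y0, x1, y1, ...] lists where x is the column
    and y the row; the centre of pixel (row r, col c) is at (x=c, y=r).
    """
    xy = np.asarray(coords, dtype=float).reshape(-1, 2)
    poly = shapely.Polygon(xy)
    rr, cc = np.mgrid[0:height, 0:width]
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
    return inside.reshape(height, width)


def import_coco_masks(
    path: str | Path, series: FrameSeries
) -> list[list[np.ndarray]]:
    """Import instance masks from a COCO annotation JSON.

    COCO image entries are mapped to frame indices by file-name order.
    Polygon segmentations are rasterized so that pixel centres inside or on
    the polygon boundary count as foreground; uncompressed RLE segmentations
    are decoded directly.  Returns one list of boolean masks per frame.
    """
    with open(path) as fh:
        doc = json.load(fh)

    images = sorted(doc.get("images", []), key=lambda im: im.get("file_name", ""))
    if len(images) > series.n_frames:
        raise ValueError(
            f"COCO file lists {len(images)} images but series has "
            f"{series.n_frames} frames"
        )
    id_to_frame = {im["id"]: idx for idx, im in enumerate(images)}
    height, width = series.shape

    masks: list[list[np.ndarray]] = [[] for _ in range(series.n_frames)]
    annotations = sorted(doc.get("annotations", []), key=lambda a: a.get("id", 0))
    for ann in annotations:
        img_id = ann.get("image_id")
        if img_id not in id_to_frame:
            raise ValueError(
                f"annotation {ann.get('id')} references unknown image id {img_id}"
            )
        seg = ann.get("segmentation")
        if isinstance(seg, dict):
            h, w = seg.get("size", (height, width))
            if (h, w) != (height, width):
                raise ValueError(
                    f"annotation {ann.get('id')}: RLE size {(h, w)} does not "
                    f"match frame shape {(height, width)}"
                )
            mask = _decode_rle(seg["counts"], height, width)
        else:
            mask = np.zeros((height, width), dtype=bool)
            for coords in seg:
                arr = np.asarray(coords, dtype=float)
                if arr.min() < -0.5 or arr[0::2].max() > width - 0.5 or arr[1::2].max() > height - 0.5:
                    raise ValueError(
                        f"annotation {ann.get('id')}: polygon extends outside "
                        f"frame bounds {(height, width)}"
                    )
                mask |= _rasterize_polygon(coords, height, width)
        masks[id_to_frame[img_id]].append(mask)
    return masks
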