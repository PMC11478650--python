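"""Per-tile detector contract and reference implementations.

A detector is anything with ``detect(tile_image, tile) -> list[Detection]``
returning tile-local boxes with confidences in [0, 1].  The trained network
that would normally fill this role enters the pipeline through files (see
:func:`load_detections`); the implementations here exist so the stitching
and counting stages can be exercised and verified without any model:

* :class:`OracleDetector` — returns ground-truth head boxes clipped to each
  tile.  A truth box straddling a tile boundary yields clipped fragments in
  every tile it touches, which is exactly the duplication scenario the
  stitcher must undo.
* :class:`BlobDetector` — a classical intensity-blob detector (threshold,
  connected components, area filter) adequate for well-separated larvae.
* :class:`CapacityLimitedDetector` — wraps another detector and caps how
  many detections survive per tile, emulating how a fixed-resolution
  detector saturates on crowded inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .boxes import Box
from .formats import (
    FormatError,
    box_to_yolo_line,
    read_detection_csv,
    read_yolo_txt,
    write_detection_csv,
)
from .tiling import Tile, TileGrid, to_local

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class Detection:
    """A detected box in tile-local coordinates with a confidence score."""

    box: Box
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


class DetectorContract(Protocol):
    def detect(self, tile_image: np.ndarray, tile: Tile) -> List[Detection]: ...


# ---------------------------------------------------------------------------
# ground-truth oracle
# ---------------------------------------------------------------------------


class OracleDetector:
    """Returns every truth box intersecting a tile, clipped and tile-local.

    Scores are 1.0.  Used to verify stitching correctness independently of
    detection quality: the stitcher must recover the exact truth count from
    these deliberately duplicated fragments.
    """

    def __init__(self, truth_boxes: Sequence[Box]):
        self.truth_boxes = list(truth_boxes)
        self._x0 = np.array([b.x_min for b in truth_boxes], dtype=float)
        self._y0 = np.array([b.y_min for b in truth_boxes], dtype=float)
        self._x1 = np.array([b.x_max for b in truth_boxes], dtype=float)
        self._y1 = np.array([b.y_max for b in truth_boxes], dtype=float)

    def detect(self, tile_image: np.ndarray, tile: Tile) -> List[Detection]:
        tb = tile.bounds
        hit = np.nonzero(
            (self._x0 < tb.x_max)
            & (self._x1 > tb.x_min)
            & (self._y0 < tb.y_max)
            & (self._y1 > tb.y_min)
        )[0]
        out = []
        for i in hit:
            clipped = Box(
                max(self._x0[i], tb.x_min),
                max(self._y0[i], tb.y_min),
                min(self._x1[i], tb.x_max),
                min(self._y1[i], tb.y_max),
            )
            out.append(Detection(box=to_local(clipped, tile), score=1.0))
        return out


def oracle_detect(scene_truth: Sequence[Box], tile: Tile) -> List[Detection]:
    """Functional form of :class:`OracleDetector` for a single tile."""
    return OracleDetector(scene_truth).detect(np.empty((0, 0)), tile)


# ---------------------------------------------------------------------------
# classical blob detector
# ---------------------------------------------------------------------------


@dataclass
class BlobDetector:
    """Threshold -> connected components -> area-filtered bounding boxes.

    Defaults bracket a ~10x10 px larval head: components between 20 and
    400 px survive.  ``min_prominence`` rejects components whose peak
    intensity barely clears the threshold (noise speckle on empty tiles);
    with ``threshold_mode='otsu'`` the detections are invariant to adding a
    constant intensity offset.  Score is the component's mean intensity
    normalised by 255.
    """

    threshold_mode: str = "otsu"  # or "fixed"
    fixed_threshold: float = 128.0
    min_area_px: int = 20
    max_area_px: int = 400
    min_prominence: float = 20.0
    smooth_sigma: float = 1.0

    def detect(self, tile_image: np.ndarray, tile: Tile) -> List[Detection]:
        img = np.asarray(tile_image, dtype=float)
        if img.size == 0 or float(img.max() - img.min()) < 1e-9:
            return []  # degenerate constant tile: nothing to segment
        if self.smooth_sigma > 0:
            img = gaussian(img, sigma=self.smooth_sigma, preserve_range=True)
        if self.threshold_mode == "otsu":
            thr = float(threshold_otsu(img))
        elif self.threshold_mode == "fixed":
            thr = float(self.fixed_threshold)
        else:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        mask = img > thr
        if not mask.any():
            return []
        labels = label(mask, connectivity=2)
        out: List[Detection] = []
        for region in regionprops(labels, intensity_image=img):
            if not (self.min_area_px <= region.area <= self.max_area_px):
                continue
            if float(region.intensity_max) < thr + self.min_prominence:
                continue
            minr, minc, maxr, maxc = region.bbox  # half-open, matches Box
            score = min(1.0, max(0.0, float(region.intensity_mean) / 255.0))
            out.append(Detection(box=Box(minc, minr, maxc, maxr), score=score))
        return out


def blob_detect(
    tile_image: np.ndarray,
    threshold_mode: str = "otsu",
    min_area_px: int = 20,
    max_area_px: int = 400,
    **kwargs,
) -> List[Detection]:
    """Functional form of :class:`BlobDetector` (tile geometry not needed)."""
    det = BlobDetector(
        threshold_mode=threshold_mode,
        min_area_px=min_area_px,
        max_area_px=max_area_px,
        **kwargs,
    )
    h, w = np.asarray(tile_image).shape[:2]
    return det.detect(tile_image, Tile(row=0, col=0, origin=(0, 0), width_px=w, height_px=h))


# ---------------------------------------------------------------------------
# capacity-limited wrapper
# ---------------------------------------------------------------------------


@dataclass
class CapacityLimitedDetector:
    """Cap the number of detections a tile may return.

    The per-tile budget is ``floor(capacity_per_kilopixel * A / 1000)`` where
    ``A`` is the tile's own area, or ``reference_area_px`` when given.  The
    latter models a detector with a fixed input resolution: whatever the tile
    size, the crop is resized to the same input raster, so the number of
    objects the detector can resolve per tile is constant and crowded large
    tiles saturate first — the degradation that motivates shrinking tiles in
    the first place.  Surplus detections are dropped lowest-score first
    (ties broken by position, deterministically).
    """

    inner: DetectorContract
    capacity_per_kilopixel: float
    reference_area_px: Optional[float] = None

    def __post_init__(self) -> None:
        if self.capacity_per_kilopixel <= 0:
            raise ValueError("capacity_per_kilopixel must be > 0")

    def budget(self, tile: Tile) -> int:
        area = (
            float(self.reference_area_px)
            if self.reference_area_px is not None
            else float(tile.width_px * tile.height_px)
        )
        return int(math.floor(self.capacity_per_kilopixel * area / 1000.0))

    def detect(self, tile_image: np.ndarray, tile: Tile) -> List[Detection]:
        dets = self.inner.detect(tile_image, tile)
        k = self.budget(tile)
        if len(dets) <= k:
            return dets
        ranked = sorted(
            dets, key=lambda d: (-d.score, d.box.y_min, d.box.x_min, d.box.y_max, d.box.x_max)
        )
        return ranked[:k]


def capacity_limited_detect(
    inner: DetectorContract,
    capacity_per_kilopixel: float,
    reference_area_px: Optional[float] = None,
) -> CapacityLimitedDetector:
    return CapacityLimitedDetector(inner, capacity_per_kilopixel, reference_area_px)


# ---------------------------------------------------------------------------
# file-based detections (externally trained models)
# ---------------------------------------------------------------------------


class PrecomputedDetector:
    """Serves detections loaded from files, keyed by (tile_row, tile_col)."""

    def __init__(self, per_tile: Dict[Tuple[int, int], List[Detection]]):
        self.per_tile = per_tile

    def detect(self, tile_image: np.ndarray, tile: Tile) -> List[Detection]:
        return self.per_tile.get((tile.row, tile.col), [])


def _validate_local(det: Detection, tile: Tile, where: str) -> Detection:
    b = det.box
    if b.x_min < -1e-6 or b.y_min < -1e-6 or b.x_max > tile.width_px + 1e-6 or b.y_max > tile.height_px + 1e-6:
        raise FormatError(f"{where}: detection {b} outside tile bounds "
                          f"{tile.width_px}x{tile.height_px}")
    return det


def load_detections(
    path: Path,
    grid: TileGrid,
    format: str = "yolo_txt_per_tile",
) -> Dict[Tuple[int, int], List[Detection]]:
    """Load per-tile detections from disk.

    ``yolo_txt_per_tile``: ``path`` is a directory of ``tile_{row}_{col}.txt``
    files, coordinates normalised to each tile's own (possibly remainder)
    size.  A missing tile file means zero detections (logged).
    ``global_csv``: a single CSV of global boxes with tile ids; boxes are
    mapped back to tile-local coordinates.
    """
    path = Path(path)
    per_tile: Dict[Tuple[int, int], List[Detection]] = {}
    if format == "yolo_txt_per_tile":
        for tile in grid:
            f = path / f"tile_{tile.row}_{tile.col}.txt"
            if not f.exists():
                logger.warning("missing tile detection file %s; assuming zero detections", f)
                continue
            dets = []
            for _cls, box, score in read_yolo_txt(f, tile.width_px, tile.height_px):
                det = Detection(box=box, score=1.0 if score is None else score)
                dets.append(_validate_local(det, tile, str(f)))
            per_tile[(tile.row, tile.col)] = dets
    elif format == "global_csv":
        for box, score, row, col in read_detection_csv(path):
            tile = grid.tile_at(row, col)
            local = to_local(box, tile)
            per_tile.setdefault((row, col), []).append(
                _validate_local(Detection(box=local, score=score), tile, str(path))
            )
    else:
        raise ValueError(f"unknown detections format {format!r}")
    return per_tile


def save_detections(
    per_tile: Dict[Tuple[int, int], List[Detection]],
    grid: TileGrid,
    path: Path,
    format: str = "yolo_txt_per_tile",
) -> None:
    """Inverse of :func:`load_detections` (writes every tile with detections)."""
    path = Path(path)
    if format == "yolo_txt_per_tile":
        path.mkdir(parents=True, exist_ok=True)
        for (row, col), dets in sorted(per_tile.items()):
            tile = grid.tile_at(row, col)
            lines = [
                box_to_yolo_line(d.box, tile.width_px, tile.height_px, score=d.score)
                for d in dets
            ]
            (path / f"tile_{row}_{col}.txt").write_text(
                "".join(line + "\n" for line in lines)
            )
    elif format == "global_csv":
        rows = []
        for (row, col), dets in sorted(per_tile.items()):
            tile = grid.tile_at(row, col)
            for d in dets:
                rows.append((d.box.translate(*tile.origin), d.score, row, col))
        write_detection_csv(rows, path)
    else:
        raise ValueError(f"unknown detections format {format!r}")
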