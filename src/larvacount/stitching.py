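"""Cross-tile stitching and deduplication of per-tile detections.

A larva cut by a tile boundary is detected once in every tile it touches,
so naively summing per-tile detections overcounts.  The correction works in
four steps:

1. **Boundary classification.** Each detection is labelled with one of nine
   classes from the set ``S = {N, U, D, L, R, RU, RD, LU, LD}`` according to
   which interior tile edges its box touches (within a tolerance).  Edges on
   the image border never count — nothing is cut there.
2. **Overlap-ratio matching.** Across every interior boundary, candidate
   duplicate pairs (bottom-touching vs top-touching across a horizontal
   boundary; right- vs left-touching across a vertical one) are scored with
   the overlap ratio Ro — shared extent along the boundary divided by the
   shorter box's extent — and matched greedily, highest Ro first, one
   partner per record per boundary.  Accepted pairs merge transitively into
   clusters; a larva cut at a grid corner forms one four-member cluster.
3. **Dedup regions.** Each cluster is enclosed by its minimum bounding
   rectangle plus a small margin, clipped to the image.
4. **Re-detection.** Each region is cropped from the full image and handed
   back to the detector; the fresh detections replace every original
   detection whose centre lies inside the region, so each cut larva is
   counted exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .boxes import Box
from .detectors import DetectorContract
from .tiling import Tile, TileGrid, crop, segment_image, to_global

logger = logging.getLogger(__name__)


class BoundaryClass(str, Enum):
    """Which interior tile edges a detection touches (set S)."""

    N = "N"  # undivided
    U = "U"  # top edge
    D = "D"  # bottom edge
    L = "L"  # left edge
    R = "R"  # right edge
    RU = "RU"
    RD = "RD"
    LU = "LU"
    LD = "LD"


_CLASS_FROM_EDGES = {
    (False, False, False, False): BoundaryClass.N,
    (True, False, False, False): BoundaryClass.U,
    (False, True, False, False): BoundaryClass.D,
    (False, False, True, False): BoundaryClass.L,
    (False, False, False, True): BoundaryClass.R,
    (True, False, False, True): BoundaryClass.RU,
    (False, True, False, True): BoundaryClass.RD,
    (True, False, True, False): BoundaryClass.LU,
    (False, True, True, False): BoundaryClass.LD,
}

#: classes that can participate on each side of a boundary
_TOUCHES_RIGHT = {BoundaryClass.R, BoundaryClass.RU, BoundaryClass.RD}
_TOUCHES_LEFT = {BoundaryClass.L, BoundaryClass.LU, BoundaryClass.LD}
_TOUCHES_BOTTOM = {BoundaryClass.D, BoundaryClass.LD, BoundaryClass.RD}
_TOUCHES_TOP = {BoundaryClass.U, BoundaryClass.LU, BoundaryClass.RU}


@dataclass(frozen=True, slots=True)
class DetectionRecord:
    """A detection mapped to global coordinates with its provenance."""

    global_box: Box
    score: float
    tile: Tuple[int, int]  # (row, col)
    boundary_class: BoundaryClass


@dataclass(frozen=True, slots=True)
class MatchPair:
    a: DetectionRecord
    b: DetectionRecord
    ro: float


@dataclass(frozen=True)
class DedupRegion:
    """Minimum enclosing rectangle over a matched cluster, slated for
    re-detection."""

    rect: Box
    members: Tuple[DetectionRecord, ...]


@dataclass
class CountResult:
    final_boxes: List[Box]
    final_scores: List[float]
    total_count: int
    n_raw_detections: int
    n_clusters: int
    n_dedup_regions: int


# ---------------------------------------------------------------------------
# boundary classification
# ---------------------------------------------------------------------------


def classify_boundary(
    box: Box, tile: Tile, grid: TileGrid, tolerance_px: float = 2.0
) -> BoundaryClass:
    """Assign the boundary class of a tile-local detection box.

    An edge "touches" when the box side is within ``tolerance_px`` of the
    tile edge AND that edge is interior to the image (a neighbouring tile
    exists across it).  If three or more edges touch, the nearest edge of
    each axis wins and a warning is logged.
    """
    d_u = box.y_min
    d_d = tile.height_px - box.y_max
    d_l = box.x_min
    d_r = tile.width_px - box.x_max
    u = d_u <= tolerance_px and tile.row > 0
    d = d_d <= tolerance_px and tile.row < grid.n_rows - 1
    l = d_l <= tolerance_px and tile.col > 0
    r = d_r <= tolerance_px and tile.col < grid.n_cols - 1
    if u and d:
        logger.warning("box %s spans tile %s vertically; keeping nearest edge", box, tile)
        u, d = (d_u <= d_d), (d_d < d_u)
    if l and r:
        logger.warning("box %s spans tile %s horizontally; keeping nearest edge", box, tile)
        l, r = (d_l <= d_r), (d_r < d_l)
    return _CLASS_FROM_EDGES[(u, d, l, r)]


# ---------------------------------------------------------------------------
# overlap ratio (Ro)
# ---------------------------------------------------------------------------


def overlap_ratio(a: Box, b: Box, axis: str) -> float:
    """Overlap ratio of two candidate duplicates along the boundary axis.

    ``axis='horizontal'`` compares the x-intervals (the case of a horizontal
    boundary between vertically adjacent tiles); ``axis='vertical'`` the
    y-intervals.  Ro = intersection length / length of the shorter interval,
    clamped to [0, 1]; 0 when the intervals are disjoint.
    """
    if axis == "horizontal":
        a0, a1, b0, b1 = a.x_min, a.x_max, b.x_min, b.x_max
    elif axis == "vertical":
        a0, a1, b0, b1 = a.y_min, a.y_max, b.y_min, b.y_max
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    len_a, len_b = a1 - a0, b1 - b0
    if len_a <= 0 or len_b <= 0:
        raise ValueError("zero-length interval in overlap_ratio")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(1.0, inter / min(len_a, len_b))


# ---------------------------------------------------------------------------
# duplicate matching
# ---------------------------------------------------------------------------


def _center_distance(a: DetectionRecord, b: DetectionRecord) -> float:
    (ax, ay), (bx, by) = a.global_box.center, b.global_box.center
    return float(np.hypot(ax - bx, ay - by))


def match_duplicates(
    records: Sequence[DetectionRecord],
    grid: TileGrid,
    ro_min: float = 0.25,
) -> List[List[DetectionRecord]]:
    """Cluster detections that are fragments of the same cut object.

    For each interior boundary, candidate pairs are formed between records
    touching it from either side; pairs with Ro >= ``ro_min`` are accepted
    greedily in descending Ro (ties: smaller centroid distance, then tile
    id / record order), each record matching at most once per boundary.
    Accepted pairs merge transitively; returned clusters have >= 2 members
    and preserve input order internally.  Deterministic for fixed input.
    """
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # index records by tile
    by_tile: Dict[Tuple[int, int], List[int]] = {}
    for i, rec in enumerate(records):
        by_tile.setdefault(rec.tile, []).append(i)

    def greedy_match(side_a: List[int], side_b: List[int], axis: str) -> None:
        pairs = []
        for i in side_a:
            for j in side_b:
                ro = overlap_ratio(records[i].global_box, records[j].global_box, axis)
                if ro >= ro_min:
                    pairs.append((ro, _center_distance(records[i], records[j]), i, j))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
        used_a, used_b = set(), set()
        for ro, _dist, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            union(i, j)

    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            here = by_tile.get((row, col), [])
            if col + 1 < grid.n_cols:  # vertical boundary to the right neighbour
                right = by_tile.get((row, col + 1), [])
                side_a = [i for i in here if records[i].boundary_class in _TOUCHES_RIGHT]
                side_b = [j for j in right if records[j].boundary_class in _TOUCHES_LEFT]
                if side_a and side_b:
                    greedy_match(side_a, side_b, axis="vertical")
            if row + 1 < grid.n_rows:  # horizontal boundary to the lower neighbour
                below = by_tile.get((row + 1, col), [])
                side_a = [i for i in here if records[i].boundary_class in _TOUCHES_BOTTOM]
                side_b = [j for j in below if records[j].boundary_class in _TOUCHES_TOP]
                if side_a and side_b:
                    greedy_match(side_a, side_b, axis="horizontal")

    clusters: Dict[int, List[DetectionRecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(records[i])
    return [members for root, members in sorted(clusters.items()) if len(members) >= 2]


# ---------------------------------------------------------------------------
# dedup regions and re-detection
# ---------------------------------------------------------------------------


def build_dedup_region(
    cluster: Sequence[DetectionRecord],
    margin_px: float,
    image_bounds: Box,
) -> DedupRegion:
    """Minimum enclosing rectangle of a cluster, expanded and clipped."""
    if len(cluster) < 2:
        raise ValueError(f"dedup region requires >= 2 members, got {len(cluster)}")
    rect = Box.enclosing(r.global_box for r in cluster).expand(margin_px)
    clipped = rect.clip(image_bounds)
    assert clipped is not None  # members lie inside the image
    return DedupRegion(rect=clipped, members=tuple(cluster))


def merge_overlapping_regions(regions: Sequence[DedupRegion]) -> List[DedupRegion]:
    """Merge regions whose rectangles intersect until all are disjoint.

    Two straddling larvae close together can produce intersecting regions;
    re-detecting each separately would see (and count) the neighbour twice.
    """
    merged = list(regions)
    changed = True
    while changed:
        changed = False
        out: List[DedupRegion] = []
        for region in merged:
            for k, existing in enumerate(out):
                if region.rect.intersects(existing.rect):
                    out[k] = DedupRegion(
                        rect=Box.enclosing([existing.rect, region.rect]),
                        members=existing.members + region.members,
                    )
                    changed = True
                    break
            else:
                out.append(region)
        merged = out
    return merged


#: context ring around a dedup region for re-detection; wide enough that an
#: object whose centre is near the region is never clipped by the crop edge,
#: so centre-in-region filtering sees true centres
REDETECT_CONTEXT_PX = 32


def _region_tile(region: DedupRegion, image_shape: Tuple[int, int], context_px: float) -> Tile:
    # present a context-padded crop to the detector as a pseudo-tile
    height, width = image_shape
    x0 = max(0, int(np.floor(region.rect.x_min - context_px)))
    y0 = max(0, int(np.floor(region.rect.y_min - context_px)))
    x1 = min(width, int(np.ceil(region.rect.x_max + context_px)))
    y1 = min(height, int(np.ceil(region.rect.y_max + context_px)))
    return Tile(row=-1, col=-1, origin=(x0, y0), width_px=x1 - x0, height_px=y1 - y0)


def resolve_regions(
    image: np.ndarray,
    regions: Sequence[DedupRegion],
    detector: DetectorContract,
    context_px: float = REDETECT_CONTEXT_PX,
) -> List[List[Tuple[Box, float]]]:
    """Re-detect inside each dedup region.

    The detector sees the region plus a ``context_px`` ring so objects near
    the region edge are detected whole; only re-detections whose centres lie
    inside the region itself are kept — an object merely clipped by the
    region still belongs to its surviving original detection outside.  If
    the detector fails on a crop, the region falls back to counting its
    cluster as a single object.
    """
    results: List[List[Tuple[Box, float]]] = []
    for region in regions:
        tile = _region_tile(region, image.shape[:2], context_px)
        try:
            tile_img = crop(image, tile)
            dets = detector.detect(tile_img, tile)
            kept = []
            for det in dets:
                g = to_global(det.box, tile)
                if region.rect.contains_point(*g.center):
                    kept.append((g, det.score))
            results.append(kept)
        except Exception as exc:  # detector failure: count the cluster once
            logger.warning(
                "detector failed on dedup region %s (%s); counting cluster as one object",
                region.rect,
                exc,
            )
            rep = Box.enclosing(m.global_box for m in region.members)
            score = max(m.score for m in region.members)
            results.append([(rep, score)])
    return results


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _centers_in_regions(records: Sequence[DetectionRecord], regions: Sequence[DedupRegion]) -> np.ndarray:
    """Boolean mask: record centre lies inside some region (vectorised)."""
    removed = np.zeros(len(records), dtype=bool)
    if not records or not regions:
        return removed
    cx = np.array([r.global_box.center[0] for r in records])
    cy = np.array([r.global_box.center[1] for r in records])
    chunk = 256
    rx0 = np.array([g.rect.x_min for g in regions])
    ry0 = np.array([g.rect.y_min for g in regions])
    rx1 = np.array([g.rect.x_max for g in regions])
    ry1 = np.array([g.rect.y_max for g in regions])
    for s in range(0, len(regions), chunk):
        inside = (
            (cx[:, None] >= rx0[None, s : s + chunk])
            & (cx[:, None] < rx1[None, s : s + chunk])
            & (cy[:, None] >= ry0[None, s : s + chunk])
            & (cy[:, None] < ry1[None, s : s + chunk])
        )
        removed |= inside.any(axis=1)
    return removed


def collect_records(
    image: np.ndarray,
    grid: TileGrid,
    detector: DetectorContract,
    tolerance_px: float = 2.0,
) -> List[DetectionRecord]:
    """Run the detector on every tile and map detections to global records."""
    records: List[DetectionRecord] = []
    for tile in grid:
        tile_img = crop(image, tile)
        for det in detector.detect(tile_img, tile):
            cls = classify_boundary(det.box, tile, grid, tolerance_px)
            records.append(
                DetectionRecord(
                    global_box=to_global(det.box, tile),
                    score=det.score,
                    tile=(tile.row, tile.col),
                    boundary_class=cls,
                )
            )
    return records


def count_image(
    image: np.ndarray,
    tile_size: int,
    detector: DetectorContract,
    tolerance_px: float = 2.0,
    ro_min: float = 0.25,
    margin_px: float = 4.0,
    no_dedup: bool = False,
) -> CountResult:
    """Full counting pipeline: segment, detect per tile, stitch, dedup.

    With ``no_dedup=True`` the pipeline stops after mapping detections to
    global coordinates (the ablation baseline that double counts boundary
    objects).
    """
    height, width = image.shape[:2]
    grid = segment_image(width, height, tile_size)
    records = collect_records(image, grid, detector, tolerance_px)
    n_raw = len(records)
    if no_dedup:
        boxes = [r.global_box for r in records]
        scores = [r.score for r in records]
        return CountResult(boxes, scores, len(boxes), n_raw, 0, 0)

    clusters = match_duplicates(records, grid, ro_min)
    image_bounds = Box(0, 0, width, height)
    regions = [build_dedup_region(c, margin_px, image_bounds) for c in clusters]
    regions = merge_overlapping_regions(regions)
    region_results = resolve_regions(image, regions, detector)

    removed = _centers_in_regions(records, regions)
    final_boxes: List[Box] = []
    final_scores: List[float] = []
    for rec, gone in zip(records, removed):
        if not gone:
            final_boxes.append(rec.global_box)
            final_scores.append(rec.score)
    for per_region in region_results:
        for box, score in per_region:
            final_boxes.append(box)
            final_scores.append(score)

    return CountResult(
        final_boxes=final_boxes,
        final_scores=final_scores,
        total_count=len(final_boxes),
        n_raw_detections=n_raw,
        n_clusters=len(clusters),
        n_dedup_regions=len(regions),
    )
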