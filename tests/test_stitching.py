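import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvacount import (
    Box,
    BoundaryClass,
    DetectionRecord,
    OracleDetector,
    SceneConfig,
    build_dedup_region,
    classify_boundary,
    count_image,
    generate_scene,
    match_duplicates,
    merge_overlapping_regions,
    overlap_ratio,
    resolve_regions,
    segment_image,
    straddle_census,
)
from larvacount.stitching import collect_records


class TestClassifyBoundary:
    def setup_method(self):
        self.grid = segment_image(300, 300, 100)  # 3x3, tile (1,1) fully interior

    def test_interior_box_is_n(self):
        tile = self.grid.tile_at(1, 1)
        assert classify_boundary(Box(40, 10, 50, 20), tile, self.grid, 2) == BoundaryClass.N

    def test_bottom_touch_interior_vs_image_border(self):
        box = Box(40, 95, 50, 100)
        interior = self.grid.tile_at(1, 1)
        bottom_row = self.grid.tile_at(2, 1)
        assert classify_boundary(box, interior, self.grid, 2) == BoundaryClass.D
        assert classify_boundary(box, bottom_row, self.grid, 2) == BoundaryClass.N

    def test_corner_touch_is_rd(self):
        tile = self.grid.tile_at(1, 1)
        assert classify_boundary(Box(95, 95, 100, 100), tile, self.grid, 2) == BoundaryClass.RD

    @pytest.mark.parametrize(
        "box,expected",
        [
            (Box(0, 40, 5, 50), BoundaryClass.L),
            (Box(95, 40, 100, 50), BoundaryClass.R),
            (Box(40, 0, 50, 5), BoundaryClass.U),
            (Box(0, 0, 5, 5), BoundaryClass.LU),
            (Box(95, 0, 100, 5), BoundaryClass.RU),
            (Box(0, 95, 5, 100), BoundaryClass.LD),
        ],
    )
    def test_all_edge_combinations(self, box, expected):
        tile = self.grid.tile_at(1, 1)
        assert classify_boundary(box, tile, self.grid, 2) == expected

    def test_tolerance_widens_touch(self):
        tile = self.grid.tile_at(1, 1)
        box = Box(40, 90, 50, 97)  # 3 px short of the bottom edge
        assert classify_boundary(box, tile, self.grid, 2) == BoundaryClass.N
        assert classify_boundary(box, tile, self.grid, 4) == BoundaryClass.D

    def test_box_spanning_tile_keeps_nearest_edges(self, caplog):
        tile = self.grid.tile_at(1, 1)
        box = Box(1, 40, 99, 50)  # touches both L and R; R is nearer
        assert classify_boundary(box, tile, self.grid, 2) == BoundaryClass.L


class TestOverlapRatio:
    def test_identical_intervals(self):
        a = Box(10, 0, 30, 5)
        assert overlap_ratio(a, Box(10, 5, 30, 10), "horizontal") == 1.0

    def test_partial_overlap_over_shorter(self):
        a = Box(10, 0, 30, 5)  # x-extent 20
        b = Box(15, 5, 35, 10)  # x-extent 20, intersection 15
        assert overlap_ratio(a, b, "horizontal") == pytest.approx(0.75)

    def test_disjoint_intervals(self):
        assert overlap_ratio(Box(0, 0, 10, 5), Box(20, 5, 30, 10), "horizontal") == 0.0

    def test_vertical_axis_uses_y(self):
        a = Box(0, 10, 5, 30)
        b = Box(5, 20, 10, 40)
        assert overlap_ratio(a, b, "vertical") == pytest.approx(0.5)

    def test_bad_axis(self):
        with pytest.raises(ValueError):
            overlap_ratio(Box(0, 0, 1, 1), Box(0, 0, 1, 1), "diagonal")

    @given(
        a0=st.floats(0, 50),
        aw=st.floats(1, 30),
        b0=st.floats(0, 50),
        bw=st.floats(1, 30),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_and_symmetric(self, a0, aw, b0, bw):
        a = Box(a0, 0, a0 + aw, 1)
        b = Box(b0, 1, b0 + bw, 2)
        ro = overlap_ratio(a, b, "horizontal")
        assert 0.0 <= ro <= 1.0
        assert ro == pytest.approx(overlap_ratio(b, a, "horizontal"))


def _records_from_truth(truth, grid):
    det = OracleDetector(truth)
    img = np.zeros((grid.image_height, grid.image_width), dtype=np.uint8)
    return collect_records(img, grid, det)


class TestMatchDuplicates:
    def test_vertical_straddle_forms_pair(self):
        grid = segment_image(200, 100, 100)
        records = _records_from_truth([Box(95, 40, 105, 50)], grid)
        clusters = match_duplicates(records, grid)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_corner_straddle_forms_four_member_cluster(self):
        grid = segment_image(200, 200, 100)
        records = _records_from_truth([Box(95, 95, 105, 105)], grid)
        clusters = match_duplicates(records, grid)
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_competing_candidates_highest_ro_wins(self):
        # one bottom-touching box in the upper tile faces two top-touching
        # boxes in the lower tile; the one with the larger overlap ratio is
        # selected, the other stays unmatched
        grid = segment_image(100, 200, 100)
        d_rec = DetectionRecord(Box(40, 95, 60, 100), 1.0, (0, 0), BoundaryClass.D)
        u_good = DetectionRecord(Box(45, 100, 58, 105), 1.0, (1, 0), BoundaryClass.U)
        u_poor = DetectionRecord(Box(30, 100, 47, 105), 1.0, (1, 0), BoundaryClass.U)
        ro_good = overlap_ratio(d_rec.global_box, u_good.global_box, "horizontal")
        ro_poor = overlap_ratio(d_rec.global_box, u_poor.global_box, "horizontal")
        assert ro_good > ro_poor >= 0.25
        clusters = match_duplicates([d_rec, u_poor, u_good], grid)
        assert clusters == [[d_rec, u_good]]

    def test_ro_floor_blocks_weak_pairs(self):
        grid = segment_image(100, 200, 100)
        d_rec = DetectionRecord(Box(40, 95, 60, 100), 1.0, (0, 0), BoundaryClass.D)
        u_far = DetectionRecord(Box(56, 100, 76, 105), 1.0, (1, 0), BoundaryClass.U)
        assert overlap_ratio(d_rec.global_box, u_far.global_box, "horizontal") < 0.25
        assert match_duplicates([d_rec, u_far], grid, ro_min=0.25) == []

    def test_two_straddlers_pair_with_their_own_fragments(self):
        grid = segment_image(200, 100, 100)
        truth = [Box(95, 20, 105, 30), Box(95, 24, 105, 34)]
        records = _records_from_truth(truth, grid)
        clusters = match_duplicates(records, grid)
        assert sorted(len(c) for c in clusters) == [2, 2]
        for cluster in clusters:
            ys = {round(r.global_box.y_min) for r in cluster}
            assert len(ys) == 1  # fragments of the same larva share y-extent

    def test_empty_input(self):
        grid = segment_image(200, 100, 100)
        assert match_duplicates([], grid) == []


class TestDedupRegions:
    def _rec(self, box):
        return DetectionRecord(box, 1.0, (0, 0), BoundaryClass.R)

    def test_min_max_rectangle(self):
        cluster = [self._rec(Box(90, 40, 100, 50)), self._rec(Box(100, 40, 110, 50))]
        region = build_dedup_region(cluster, 0, Box(0, 0, 1000, 1000))
        assert region.rect == Box(90, 40, 110, 50)

    def test_margin_expansion(self):
        cluster = [self._rec(Box(90, 40, 100, 50)), self._rec(Box(100, 40, 110, 50))]
        region = build_dedup_region(cluster, 4, Box(0, 0, 1000, 1000))
        assert region.rect == Box(86, 36, 114, 54)

    def test_clipped_at_image_edge(self):
        cluster = [self._rec(Box(0, 0, 10, 10)), self._rec(Box(10, 0, 20, 10))]
        region = build_dedup_region(cluster, 4, Box(0, 0, 100, 100))
        assert region.rect == Box(0, 0, 24, 14)

    def test_singleton_cluster_rejected(self):
        with pytest.raises(ValueError):
            build_dedup_region([self._rec(Box(0, 0, 10, 10))], 4, Box(0, 0, 100, 100))

    def test_overlapping_regions_merge(self):
        a = build_dedup_region(
            [self._rec(Box(90, 40, 100, 50)), self._rec(Box(100, 40, 110, 50))],
            4, Box(0, 0, 1000, 1000),
        )
        b = build_dedup_region(
            [self._rec(Box(90, 52, 100, 62)), self._rec(Box(100, 52, 110, 62))],
            4, Box(0, 0, 1000, 1000),
        )
        merged = merge_overlapping_regions([a, b])
        assert len(merged) == 1
        assert merged[0].rect == Box(86, 36, 114, 66)
        assert len(merged[0].members) == 4


class _EmptyDetector:
    def detect(self, tile_image, tile):
        return []


class _FailingDetector:
    def detect(self, tile_image, tile):
        raise RuntimeError("model unavailable")


class TestResolveRegions:
    def _straddler_setup(self, extra_truth=()):
        truth = [Box(95, 40, 105, 50), *extra_truth]
        grid = segment_image(200, 100, 100)
        records = _records_from_truth(truth, grid)
        clusters = match_duplicates(records, grid)
        regions = [build_dedup_region(c, 4, Box(0, 0, 200, 100)) for c in clusters]
        return truth, merge_overlapping_regions(regions)

    def test_straddler_re_detected_once(self):
        truth, regions = self._straddler_setup()
        img = np.zeros((100, 200), dtype=np.uint8)
        [result] = resolve_regions(img, regions, OracleDetector(truth))
        assert len(result) == 1
        assert result[0][0] == truth[0]

    def test_whole_larva_inside_margin_also_counted(self):
        # a second, unsplit larva whose centre falls inside the dedup region
        truth, regions = self._straddler_setup(extra_truth=[Box(93, 30, 103, 40)])
        img = np.zeros((100, 200), dtype=np.uint8)
        [result] = resolve_regions(img, regions, OracleDetector(truth))
        assert len(result) == 2

    def test_empty_region_contributes_zero(self):
        truth, regions = self._straddler_setup()
        img = np.zeros((100, 200), dtype=np.uint8)
        [result] = resolve_regions(img, regions, _EmptyDetector())
        assert result == []

    def test_detector_failure_falls_back_to_one(self, caplog):
        truth, regions = self._straddler_setup()
        img = np.zeros((100, 200), dtype=np.uint8)
        [result] = resolve_regions(img, regions, _FailingDetector())
        assert len(result) == 1


class TestCountImage:
    def test_blank_image_counts_zero(self):
        img = np.full((200, 200), 40, dtype=np.uint8)
        result = count_image(img, 100, OracleDetector([]))
        assert result.total_count == 0 and result.n_raw_detections == 0

    @pytest.mark.parametrize("tile_size", [50, 100, 150])
    def test_oracle_equivalence_small_scene(self, tile_size, make_scene):
        scene = make_scene(SceneConfig(width_px=600, height_px=600, n_larvae=120, seed=2))
        result = count_image(scene.image, tile_size, OracleDetector(scene.truth_boxes))
        assert result.total_count == 120

    def test_no_dedup_overcount_equals_straddle_census(self, make_scene):
        scene = make_scene(SceneConfig(width_px=600, height_px=600, n_larvae=120, seed=2))
        grid = segment_image(600, 600, 100)
        raw = count_image(
            scene.image, 100, OracleDetector(scene.truth_boxes), no_dedup=True
        )
        census = straddle_census(scene.truth_boxes, grid)
        assert raw.total_count == 120 + census
        assert census > 0

    def test_dedup_never_increases_count(self, make_scene):
        scene = make_scene(SceneConfig(width_px=600, height_px=600, n_larvae=120, seed=2))
        result = count_image(scene.image, 100, OracleDetector(scene.truth_boxes))
        assert result.total_count <= result.n_raw_detections

    def test_single_tile_grid_is_identity(self, make_scene):
        # one tile covering the whole image: no interior boundaries, nothing
        # to stitch, the result is the raw detection set
        scene = make_scene(SceneConfig(width_px=600, height_px=600, n_larvae=120, seed=2))
        result = count_image(scene.image, 600, OracleDetector(scene.truth_boxes))
        assert result.total_count == result.n_raw_detections == 120
        assert result.n_dedup_regions == 0

    def test_deterministic_across_runs(self, make_scene):
        scene = make_scene(SceneConfig(width_px=600, height_px=600, n_larvae=120, seed=2))
        det = OracleDetector(scene.truth_boxes)
        a = count_image(scene.image, 100, det)
        b = count_image(scene.image, 100, det)
        assert a.final_boxes == b.final_boxes
        assert a.total_count == b.total_count
        assert a.n_raw_detections == b.n_raw_detections
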