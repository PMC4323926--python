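"""Detection/tracking/feature evaluation metrics (Jaccard, SFDA, ATA)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motrack.evaluation import (BoxTrack, ata, evaluate_feature_extraction,
                                evaluate_tracking, frame_detection_accuracy,
                                jaccard, median_abs_relative_error, sfda,
                                track_correspondence, track_to_boxes)
from motrack.image_io import BoundingBox, GroundTruthTrack
from motrack.tracking import Track, TrackPoint


def box(frame, x, y, w=10.0, h=10.0):
    return BoundingBox(frame=frame, x=float(x), y=float(y), w=w, h=h)


def gt_track(gt_id, frames_xy, w=10.0):
    return GroundTruthTrack(gt_id=gt_id, boxes={
        f: box(f, x, y, w, w) for f, x, y in frames_xy})


def box_track(track_id, frames_xy, w=10.0):
    return BoxTrack(track_id=track_id, boxes={
        f: box(f, x, y, w, w) for f, x, y in frames_xy})


class TestJaccard:
    def test_identical_boxes(self):
        assert jaccard(box(0, 0, 0), box(0, 0, 0)) == 1.0

    def test_disjoint_boxes(self):
        assert jaccard(box(0, 0, 0), box(0, 50, 50)) == 0.0

    def test_half_overlap_printed_value(self):
        # [0,0,10,10] vs [5,0,10,10]: 50 / 150
        assert jaccard(box(0, 0, 0), box(0, 5, 0)) == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(0, 50) for _ in range(4)]),
           st.tuples(*[st.floats(0, 50) for _ in range(4)]),
           st.floats(1, 20), st.floats(1, 20))
    def test_symmetric_and_bounded(self, p, q, w1, w2):
        a = BoundingBox(frame=0, x=p[0], y=p[1], w=w1, h=p[2] + 1)
        b = BoundingBox(frame=0, x=q[0], y=q[1], w=w2, h=q[2] + 1)
        j1, j2 = jaccard(a, b), jaccard(b, a)
        assert j1 == pytest.approx(j2)
        assert 0.0 <= j1 <= 1.0


class TestFrameDetectionAccuracy:
    def test_perfect_detections(self):
        boxes = [box(0, 10 * i, 0) for i in range(4)]
        assert frame_detection_accuracy(boxes, list(boxes)) == 1.0

    def test_missed_detection_penalised_by_mean_count(self):
        gt = [box(0, 0, 0), box(0, 30, 0)]
        res = [box(0, 0, 0)]
        assert frame_detection_accuracy(gt, res) == pytest.approx(1 / 1.5)

    def test_empty_cases(self):
        assert frame_detection_accuracy([], []) == 1.0
        assert frame_detection_accuracy([box(0, 0, 0)], []) == 0.0
        assert frame_detection_accuracy([], [box(0, 0, 0)]) == 0.0


class TestSfdaAndAta:
    def _gt(self):
        return [gt_track(i, [(f, 20 * i + f, 5) for f in range(5)])
                for i in range(3)]

    def test_self_comparison_is_unity(self):
        gt = self._gt()
        res = [box_track(i, [(f, 20 * i + f, 5) for f in range(5)])
               for i in range(3)]
        assert sfda(gt, res) == pytest.approx(1.0)
        assert ata(gt, res) == pytest.approx(1.0)

    def test_empty_results_scores_zero(self):
        assert sfda(self._gt(), []) == 0.0
        assert ata(self._gt(), []) == 0.0

    def test_split_track_penalised_in_ata(self):
        gt = [gt_track(0, [(f, f, 5) for f in range(10)])]
        halves = [box_track(0, [(f, f, 5) for f in range(5)]),
                  box_track(1, [(f, f, 5) for f in range(5, 10)])]
        val = ata(gt, halves)
        assert val < 1.0
        # best pair covers 5 of 10 frames; denominator (1+2)/2
        assert val == pytest.approx(0.5 / 1.5)

    def test_swapping_gt_and_result_leaves_scores_unchanged(self):
        gt = self._gt()
        res = [box_track(i, [(f, 20 * i + f + 2, 6) for f in range(5)])
               for i in range(3)]
        as_gt = [GroundTruthTrack(gt_id=t.track_id, boxes=t.boxes) for t in res]
        as_res = [BoxTrack(track_id=t.gt_id, boxes=t.boxes) for t in gt]
        assert sfda(gt, res) == pytest.approx(sfda(as_gt, as_res))
        assert ata(gt, res) == pytest.approx(ata(as_gt, as_res))

    def test_threshold_rule_half_overlap_counts_as_one(self):
        # every-frame Jaccard 1/3 < 0.4 stays raw; shift for J=0.5 >= 0.4 -> 1
        gt = [gt_track(0, [(f, 0, 0) for f in range(5)], w=12.0)]
        res = [box_track(0, [(f, 4, 0) for f in range(5)], w=12.0)]
        j = jaccard(gt[0].boxes[0], res[0].boxes[0])
        assert j >= 0.4
        assert ata(gt, res, jaccard_threshold=0.4) == pytest.approx(1.0)
        assert ata(gt, res, None) == pytest.approx(j)

    def test_thresholded_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(2)
        gt = [gt_track(i, [(f, 30 * i + rng.uniform(-4, 4), rng.uniform(-4, 4))
                           for f in range(6)]) for i in range(3)]
        res = [box_track(i, [(f, 30 * i + rng.uniform(-4, 4), rng.uniform(-4, 4))
                             for f in range(6)]) for i in range(3)]
        raw = ata(gt, res, None)
        prev = raw
        for thr in (0.8, 0.6, 0.4, 0.2):
            cur = ata(gt, res, thr)
            assert cur >= raw - 1e-12
            assert cur >= prev - 1e-12  # lowering threshold never decreases
            prev = cur

    def test_crossed_similarities_resolved_globally(self):
        gt = [gt_track(0, [(f, 0, 0) for f in range(5)]),
              gt_track(1, [(f, 40, 0) for f in range(5)])]
        res = [box_track(0, [(f, 1, 0) for f in range(5)]),
               box_track(1, [(f, 41, 0) for f in range(5)])]
        corr = track_correspondence(gt, res)
        assert sorted((g, r) for g, r, _ in corr.pairs) == [(0, 0), (1, 1)]

    def test_hungarian_matches_exhaustive_search_up_to_4_tracks(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_gt, n_res = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            gt = [gt_track(i, [(f, rng.uniform(0, 40), rng.uniform(0, 40))
                               for f in range(4)]) for i in range(n_gt)]
            res = [box_track(j, [(f, rng.uniform(0, 40), rng.uniform(0, 40))
                                 for f in range(4)]) for j in range(n_res)]
            corr = track_correspondence(gt, res)
            got = sum(s for _, _, s in corr.pairs)
            # oracle: exhaustive assignment over all injective mappings
            from motrack.evaluation import _pair_score

            best = 0.0
            for perm in itertools.permutations(range(n_res), min(n_gt, n_res)):
                idx = list(range(n_gt))[: len(perm)]
                val = sum(_pair_score(gt[i], res[j], None)
                          for i, j in zip(idx, perm))
                best = max(best, val)
            if n_gt > n_res:
                for subset in itertools.permutations(range(n_gt), n_res):
                    val = sum(_pair_score(gt[i], res[j], None)
                              for j, i in enumerate(subset))
                    best = max(best, val)
            assert got == pytest.approx(best, abs=1e-9)

    def test_track_to_boxes_square_geometry(self):
        t = Track(track_id=0, points=[TrackPoint(frame=0, x=50, y=40, radius=8)])
        bt = track_to_boxes(t)
        b = bt.boxes[0]
        assert (b.x, b.y, b.w, b.h) == (42, 32, 16, 16)

    def test_report_bundles_all_metrics(self):
        gt = self._gt()
        res = [box_track(i, [(f, 20 * i + f, 5) for f in range(5)])
               for i in range(3)]
        rep = evaluate_tracking(gt, res)
        assert rep.sfda == pytest.approx(1.0)
        assert rep.ata_thresholded >= rep.ata
        assert len(rep.fda_per_frame) == 5


class TestFeatureEvaluation:
    def _frames(self, areas, jitter=0.0):
        gt, res = {}, {}
        for f in range(3):
            gt[f] = [{"id": i, "x": 20.0 * i, "y": 5.0, "area": a}
                     for i, a in enumerate(areas)]
            res[f] = [{"id": 100 + i, "x": 20.0 * i + jitter, "y": 5.0,
                       "area": a * 1.1} for i, a in enumerate(areas)]
        return gt, res

    def test_identical_features_zero_error(self):
        gt, _ = self._frames([100.0, 200.0])
        pairs = evaluate_feature_extraction(gt, gt, max_distance=5)
        assert median_abs_relative_error(pairs, "area") == 0.0

    def test_constructed_10pct_inflation(self):
        gt, res = self._frames([100.0, 200.0], jitter=1.0)
        pairs = evaluate_feature_extraction(gt, res, max_distance=5)
        assert median_abs_relative_error(pairs, "area") == pytest.approx(0.1)

    def test_distance_gate_excludes_far_pairs(self):
        gt, res = self._frames([100.0], jitter=30.0)
        pairs = evaluate_feature_extraction(gt, res, max_distance=5)
        assert len(pairs) == 0

    def test_missing_result_feature_counts_as_full_error(self):
        gt = {0: [{"id": 0, "x": 0.0, "y": 0.0, "area": 50.0}]}
        res = {0: [{"id": 1, "x": 0.0, "y": 0.0, "area": float("nan")}]}
        pairs = evaluate_feature_extraction(gt, res, max_distance=5)
        assert median_abs_relative_error(pairs, "area") == 1.0
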