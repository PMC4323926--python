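"""Tracking tiers: NN segment building, similarity, joining, editing."""

import itertools

import numpy as np
import pytest

from motrack.detection import Detection
from motrack.tracking import (EditOp, LinkParams, Segment, Track, TrackPoint,
                              edit_tracks, filter_short_tracks, join_segments,
                              link_nearest_neighbor, propose_joins,
                              segment_similarity)


def det(frame, x, y):
    return Detection(frame=frame, x=float(x), y=float(y), radius=8.0, score=1.0)


def seg(seg_id, start_frame, positions):
    return Segment(seg_id=seg_id, points=[
        (start_frame + i, det(start_frame + i, x, y))
        for i, (x, y) in enumerate(positions)])


class TestNearestNeighborLinking:
    def test_two_diverging_cells_track_unbroken(self):
        dets = []
        for t in range(5):
            dets.append(det(t, 35 - 2.5 * t, 50))
            dets.append(det(t, 65 + 2.5 * t, 50))
        segs = link_nearest_neighbor(dets, LinkParams(r=10))
        assert len(segs) == 2
        assert sorted(len(s.points) for s in segs) == [5, 5]

    def test_ambiguity_terminates_and_restarts(self):
        # one segment end sees two detections within r at frame 2; the two
        # new segments then continue unambiguously
        dets = [det(0, 50, 50), det(1, 50, 50),
                det(2, 46, 50), det(2, 54, 50),
                det(3, 40, 50), det(3, 60, 50)]
        segs = link_nearest_neighbor(dets, LinkParams(r=10))
        lengths = sorted(len(s.points) for s in segs)
        assert lengths == [2, 2, 2]
        assert sorted(s.start_frame for s in segs) == [0, 2, 2]

    def test_contested_detection_terminates_both_segments(self):
        # two segment ends converge on a single detection
        dets = [det(0, 40, 50), det(0, 60, 50),
                det(1, 44, 50), det(1, 56, 50),
                det(2, 50, 50)]
        segs = link_nearest_neighbor(dets, LinkParams(r=10))
        assert sorted(len(s.points) for s in segs) == [1, 2, 2]

    def test_empty_frame_terminates_all_segments(self):
        dets = [det(0, 10, 10), det(1, 12, 10), det(3, 14, 10), det(4, 16, 10)]
        segs = link_nearest_neighbor(dets, LinkParams(r=10))
        assert len(segs) == 2
        assert sorted((s.start_frame, s.end_frame) for s in segs) == [
            (0, 1), (3, 4)]

    def test_out_of_range_detection_starts_new_segment(self):
        dets = [det(0, 10, 10), det(1, 40, 10)]
        segs = link_nearest_neighbor(dets, LinkParams(r=10))
        assert len(segs) == 2

    def test_no_detection_duplicated_or_dropped(self):
        rng = np.random.default_rng(3)
        dets = [det(t, *rng.uniform(0, 100, 2)) for t in range(8)
                for _ in range(6)]
        segs = link_nearest_neighbor(dets, LinkParams(r=12))
        seen = [(f, d.x, d.y) for s in segs for f, d in s.points]
        assert len(seen) == len(dets)
        assert len(set(seen)) == len(seen)

    def test_segments_are_frame_contiguous(self):
        rng = np.random.default_rng(4)
        dets = [det(t, *rng.uniform(0, 80, 2)) for t in range(10)
                for _ in range(4)]
        for s in link_nearest_neighbor(dets, LinkParams(r=15)):
            frames = [f for f, _ in s.points]
            assert frames == list(range(frames[0], frames[-1] + 1))


class TestSegmentSimilarity:
    P = LinkParams(max_gap=4, v_max=10.0, join_threshold=0.4,
                   w_time=0.25, w_space=0.5, w_speed=0.25)

    def test_temporal_overlap_is_infeasible(self):
        a = seg(0, 0, [(0, 0), (1, 0), (2, 0)])
        b = seg(1, 1, [(5, 5), (6, 5)])
        assert segment_similarity(a, b, self.P) == 0.0

    def test_perfect_continuation_scores_one(self):
        a = seg(0, 8, [(0, 0), (5, 0), (10, 0)])     # ends frame 10 at (10,0)
        b = seg(1, 11, [(10, 0), (15, 0), (20, 0)])  # starts where a ended
        # gap 1, distance 0, equal mean speeds -> every term is 1
        assert segment_similarity(a, b, self.P) == pytest.approx(1.0)

    def test_weighted_sum_hand_value(self):
        # a ends frame 10 at (0,0) with mean step 5; b starts frame 12 at
        # (8,0) with mean step 5.  gap=2: s_time=1-1/4, s_space=1-8/20,
        # s_speed=1 -> 0.25*0.75 + 0.5*0.6 + 0.25*1 = 0.7375
        a = seg(0, 8, [(-10, 0), (-5, 0), (0, 0)])
        b = seg(1, 12, [(8, 0), (13, 0), (18, 0)])
        assert segment_similarity(a, b, self.P) == pytest.approx(0.7375)

    def test_gap_beyond_max_or_distance_beyond_speed_bound_is_zero(self):
        a = seg(0, 0, [(0, 0), (1, 0)])
        far_in_time = seg(1, 7, [(2, 0), (3, 0)])     # gap 6 > 4
        far_in_space = seg(2, 3, [(50, 0), (51, 0)])  # 49 px > 10*2
        assert segment_similarity(a, far_in_time, self.P) == 0.0
        assert segment_similarity(a, far_in_space, self.P) == 0.0


def brute_force_joins(segments, params):
    """Exhaustive search over all feasible join matchings (oracle).

    Maximises sum over accepted joins of (similarity − threshold), the same
    objective the padded Hungarian solves.
    """
    from motrack.tracking import resolve_v_max

    v_max = resolve_v_max(segments, params)
    n = len(segments)
    feasible = [
        (i, j, segment_similarity(segments[i], segments[j], params, v_max=v_max))
        for i in range(n) for j in range(n) if i != j
    ]
    feasible = [(i, j, s) for i, j, s in feasible if s > params.join_threshold]
    best_val, best_set = 0.0, []
    for k in range(len(feasible) + 1):
        for combo in itertools.combinations(feasible, k):
            rows = [c[0] for c in combo]
            cols = [c[1] for c in combo]
            if len(set(rows)) < len(rows) or len(set(cols)) < len(cols):
                continue
            val = sum(c[2] - params.join_threshold for c in combo)
            if val > best_val + 1e-12:
                best_val, best_set = val, list(combo)
    return best_val, best_set


class TestJoinSegments:
    def test_all_below_threshold_keeps_segments_apart(self):
        params = LinkParams(v_max=10.0, join_threshold=0.99)
        segs = [seg(0, 0, [(0, 0), (5, 0)]), seg(1, 3, [(30, 0), (35, 0)])]
        tracks = join_segments(segs, params)
        assert len(tracks) == 2

    def test_crossing_tracks_rejoined_by_speed_globally(self):
        # two broken tracks whose broken ends are spatially interchangeable;
        # the speed term disambiguates, and the global optimum must beat the
        # greedy distance-only choice
        params = LinkParams(v_max=20.0, join_threshold=0.3)
        slow_a = seg(0, 0, [(0, 0), (1, 0), (2, 0)])
        fast_a = seg(1, 0, [(0, 30), (10, 30), (20, 30)])
        # both continuations start near (30, 15), equidistant from both ends
        slow_b = seg(2, 4, [(4, 14), (5, 14), (6, 14)])
        fast_b = seg(3, 4, [(40, 16), (50, 16), (60, 16)])
        joins = propose_joins([slow_a, fast_a, slow_b, fast_b], params)
        assert (0, 2) in [(i, j) for i, j, _ in joins]
        assert (1, 3) in [(i, j) for i, j, _ in joins]

    def test_matches_exhaustive_enumeration_up_to_6_segments(self):
        rng = np.random.default_rng(9)
        params = LinkParams(r=15, v_max=12.0, join_threshold=0.4, max_gap=4)
        for trial in range(12):
            segs = []
            for k in range(6):
                start = int(rng.integers(0, 10))
                n_pts = int(rng.integers(2, 5))
                x0, y0 = rng.uniform(0, 60, 2)
                step = rng.uniform(1, 8)
                segs.append(seg(k, start, [(x0 + step * i, y0)
                                           for i in range(n_pts)]))
            joins = propose_joins(segs, params)
            got = sum(s - params.join_threshold for _, _, s in joins)
            want, _ = brute_force_joins(segs, params)
            assert got == pytest.approx(want, abs=1e-9)

    def test_chained_joins_become_one_track_with_gaps_kept(self):
        params = LinkParams(v_max=10.0, join_threshold=0.3)
        s1 = seg(0, 0, [(0, 0), (2, 0), (4, 0)])
        s2 = seg(1, 5, [(8, 0), (10, 0), (12, 0)])
        s3 = seg(2, 10, [(18, 0), (20, 0)])
        (track,) = join_segments([s1, s2, s3], params)
        frames = [p.frame for p in track.points]
        assert frames == [0, 1, 2, 5, 6, 7, 10, 11]


class TestFilterAndEdit:
    def test_track_length_filter_default_five(self):
        tracks = [Track(track_id=i, points=[
            TrackPoint(frame=f, x=0, y=0) for f in range(n)])
            for i, n in enumerate([3, 4, 5, 6])]
        kept = filter_short_tracks(tracks, LinkParams(min_track_len=5))
        assert [len(t) for t in kept] == [5, 6]
        assert filter_short_tracks(tracks, LinkParams(min_track_len=1)) == tracks
        assert filter_short_tracks([], LinkParams()) == []

    def _ten(self):
        return Track(track_id=0, points=[
            TrackPoint(frame=f, x=float(f), y=0.0) for f in range(10)])

    def test_split_partitions_at_frame(self):
        out = edit_tracks([self._ten()], [EditOp("split", 0, 5)])
        assert sorted(len(t) for t in out) == [5, 5]
        by_id = {t.track_id: t for t in out}
        assert by_id[0].end_frame == 4 and by_id[1].start_frame == 5

    def test_split_then_join_restores_original(self):
        out = edit_tracks([self._ten()],
                          [EditOp("split", 0, 5), EditOp("join", 0, 1)])
        assert len(out) == 1
        assert [p.frame for p in out[0].points] == list(range(10))

    def test_join_of_overlapping_tracks_rejected(self):
        t0 = self._ten()
        t1 = Track(track_id=1, points=[TrackPoint(frame=f, x=0, y=0)
                                       for f in range(5, 12)])
        with pytest.raises(ValueError, match="overlap"):
            edit_tracks([t0, t1], [EditOp("join", 0, 1)])

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            edit_tracks([self._ten()], [EditOp("join", 0, 7)])
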