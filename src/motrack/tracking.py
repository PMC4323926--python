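"""Two-tier tracking: confident nearest-neighbour segments, then global joining.

Tier one links detections frame-to-frame only when the association is
unambiguous (exactly one mutual candidate within the link radius ``r``);
any ambiguity — two candidates for one segment end, or one detection claimed
by two ends — terminates the segments involved and opens fresh ones, so each
segment is a stretch over which the tracker is confident.  Tier two scores
every feasible predecessor/successor segment pair by a compatibility
similarity (gap, end-to-start distance, speed agreement) and solves a global
one-to-one assignment with the Hungarian algorithm, joining only pairs whose
similarity exceeds a threshold.  Joined tracks keep their frame gaps: no
positions are interpolated, and downstream speed computations use the actual
elapsed time across a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, NamedTuple, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection

_EPS = 1e-9


class TrackPoint(NamedTuple):
    frame: int
    x: float
    y: float
    radius: float = float("nan")


@dataclass
class Segment:
    """A frame-contiguous tracklet of detections."""

    seg_id: int
    points: List[tuple]  # (frame, Detection), consecutive frames

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.points]
        if not frames:
            raise ValueError("segment needs at least one point")
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("segment frames must be consecutive")

    @property
    def start_frame(self) -> int:
        return self.points[0][0]

    @property
    def end_frame(self) -> int:
        return self.points[-1][0]

    @property
    def start_pos(self) -> tuple:
        d = self.points[0][1]
        return (d.x, d.y)

    @property
    def end_pos(self) -> tuple:
        d = self.points[-1][1]
        return (d.x, d.y)

    def mean_step(self) -> float | None:
        """Mean per-frame displacement (px/frame); None for 1-point segments."""
        if len(self.points) < 2:
            return None
        steps = [
            np.hypot(b.x - a.x, b.y - a.y)
            for (_, a), (_, b) in zip(self.points, self.points[1:])
        ]
        return float(np.mean(steps))


@dataclass
class Track:
    """A joined cell track; frames strictly increasing, gaps only at joins."""

    track_id: int
    points: List[TrackPoint]

    def __post_init__(self) -> None:
        frames = [p.frame for p in self.points]
        if not frames:
            raise ValueError("track needs at least one point")
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def start_frame(self) -> int:
        return self.points[0].frame

    @property
    def end_frame(self) -> int:
        return self.points[-1].frame

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class LinkParams:
    """Parameters of both tracking tiers.

    ``v_max`` (plausible speed bound, px/frame) may be left as ``None``: it
    is then estimated from the data as 2 × the 95th percentile of
    consecutive-frame nearest-neighbour displacements (see
    :func:`resolve_v_max`).  ``min_track_len`` defaults to 5 frames: shorter
    tracks are discarded.
    """

    # maximal NN link distance: well above the per-step displacement
    # distribution of fast T cells at the reference acquisition (median
    # ~12.6 px at 10 um/min, 33.3 s, 0.439 um/px) yet below typical cell
    # spacing, so links survive fast steps without courting ambiguity
    r: float = 25.0
    max_gap: int = 4                # maximal frame gap for joining
    v_max: float | None = None      # plausible speed bound, px/frame
    join_threshold: float = 0.4     # similarity acceptance threshold
    w_time: float = 0.25            # similarity weights (sum to 1)
    w_space: float = 0.5
    w_speed: float = 0.25
    min_track_len: int = 5

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if not (0 <= self.join_threshold <= 1):
            raise ValueError("join_threshold must be in [0, 1]")
        if min(self.w_time, self.w_space, self.w_speed) < 0:
            raise ValueError("similarity weights must be nonnegative")
        if abs(self.w_time + self.w_space + self.w_speed - 1.0) > 1e-9:
            raise ValueError("similarity weights must sum to 1")
        if self.min_track_len < 1:
            raise ValueError("min_track_len must be >= 1")


def link_nearest_neighbor(detections: Sequence[Detection],
                          params: LinkParams | None = None) -> list:
    """Tier one: build confident segments by modified nearest-neighbour linking.

    An open segment end at frame t−1 is extended by a detection at frame t
    only when that detection is its single candidate within ``r`` *and* the
    detection has no other segment end within ``r``.  Any contested
    configuration terminates all segments involved and starts new one-point
    segments at the contested detections; unclaimed detections also start new
    segments.
    """
    if params is None:
        params = LinkParams()
    if not detections:
        return []
    by_frame: dict = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    # deterministic within-frame order
    for f in by_frame:
        by_frame[f].sort(key=lambda d: (d.y, d.x))
    f_lo = min(by_frame)
    f_hi = max(by_frame)

    finished: list = []
    active: list = []  # list of point lists
    next_id = 0

    def close(points):
        nonlocal next_id
        finished.append(Segment(seg_id=next_id, points=points))
        next_id += 1

    for t in range(f_lo, f_hi + 1):
        dets = by_frame.get(t, [])
        if not active:
            links = {}
        else:
            ends = np.array([[pts[-1][1].x, pts[-1][1].y] for pts in active])
            pos = np.array([[d.x, d.y] for d in dets]) if dets else np.empty((0, 2))
            if len(pos):
                dist = np.hypot(ends[:, None, 0] - pos[None, :, 0],
                                ends[:, None, 1] - pos[None, :, 1])
                in_r = dist <= params.r
            else:
                in_r = np.zeros((len(active), 0), dtype=bool)
            end_counts = in_r.sum(axis=1)   # candidates per segment end
            det_counts = in_r.sum(axis=0)   # ends in range per detection
            links = {}
            for i in range(len(active)):
                if end_counts[i] == 1:
                    j = int(np.nonzero(in_r[i])[0][0])
                    if det_counts[j] == 1:
                        links[i] = j
        still_active = []
        used = set(links.values())
        for i, pts in enumerate(active):
            if i in links:
                pts.append((t, dets[links[i]]))
                still_active.append(pts)
            else:
                close(pts)
        for j, d in enumerate(dets):
            if j not in used:
                still_active.append([(t, d)])
        active = still_active
    for pts in active:
        close(pts)
    finished.sort(key=lambda s: (s.start_frame, s.start_pos[0], s.start_pos[1]))
    return [replace(s, seg_id=i) for i, s in enumerate(finished)]


def resolve_v_max(segments: Sequence[Segment], params: LinkParams) -> float:
    """Data-driven speed bound: 2 × the 95th percentile of consecutive-frame
    nearest-neighbour displacements.

    Estimated over *all* detections in the segments, not only within-segment
    steps: within-segment steps are censored at the link radius ``r`` (the
    steps that exceeded it are precisely the ones that broke a segment), and
    a bound fitted to them would reject the very joins that matter.  The 2×
    headroom keeps tail steps — again the break-prone ones — joinable.
    """
    if params.v_max is not None:
        return params.v_max
    by_frame: dict = {}
    for s in segments:
        for f, d in s.points:
            by_frame.setdefault(f, []).append((d.x, d.y))
    nn = []
    for f in sorted(by_frame):
        if f - 1 not in by_frame:
            continue
        prev = np.asarray(by_frame[f - 1])
        for x, y in by_frame[f]:
            nn.append(float(np.min(np.hypot(prev[:, 0] - x, prev[:, 1] - y))))
    if not nn:
        return params.r
    return float(2.0 * np.percentile(nn, 95)) or params.r


def segment_similarity(a: Segment, b: Segment, params: LinkParams,
                       v_max: float | None = None) -> float:
    """Compatibility of joining segment ``b`` after segment ``a`` in [0, 1].

    Zero when infeasible (b starts at or before a's end, gap beyond
    ``max_gap``, or end-to-start distance beyond ``v_max × gap``); otherwise
    a weighted sum of gap, distance and speed-agreement terms, clamped to
    [0, 1].
    """
    if v_max is None:
        v_max = resolve_v_max([a, b], params)
    gap = b.start_frame - a.end_frame
    if gap < 1 or gap > params.max_gap:
        return 0.0
    ax, ay = a.end_pos
    bx, by = b.start_pos
    d = float(np.hypot(bx - ax, by - ay))
    if d > v_max * gap:
        return 0.0
    s_time = 1.0 - (gap - 1) / params.max_gap
    s_space = 1.0 - d / (v_max * gap)
    va, vb = a.mean_step(), b.mean_step()
    if va is None or vb is None:
        # 1-point segments carry no speed evidence: renormalise over the
        # informative terms rather than inject an arbitrary speed score
        w = params.w_time + params.w_space
        sim = (params.w_time * s_time + params.w_space * s_space) / w
    else:
        s_speed = 1.0 - abs(va - vb) / max(va, vb, _EPS)
        sim = (params.w_time * s_time + params.w_space * s_space
               + params.w_speed * s_speed)
    return float(min(max(sim, 0.0), 1.0))


def propose_joins(segments: Sequence[Segment],
                  params: LinkParams | None = None) -> list:
    """Globally optimal accepted joins as (pred_index, succ_index, similarity).

    The assignment is solved on a rectangular matrix where each predecessor
    row can also choose its private "no-join" column priced at
    ``join_threshold``; an accepted real pair therefore always beats staying
    single by more than the threshold.
    """
    if params is None:
        params = LinkParams()
    n = len(segments)
    if n < 2:
        return []
    v_max = resolve_v_max(segments, params)
    # only pairs with 1 <= gap <= max_gap are feasible; index successors by
    # start frame to avoid the full quadratic similarity sweep
    by_start: dict = {}
    for j, b in enumerate(segments):
        by_start.setdefault(b.start_frame, []).append(j)
    S = np.zeros((n, n))
    for i, a in enumerate(segments):
        for gap in range(1, params.max_gap + 1):
            for j in by_start.get(a.end_frame + gap, []):
                if i != j:
                    S[i, j] = segment_similarity(a, b := segments[j], params,
                                                 v_max=v_max)
    big_neg = -1e6
    M = np.full((n, 2 * n), big_neg)
    M[:, :n] = np.where(S > 0, S, big_neg)
    for i in range(n):
        M[i, n + i] = params.join_threshold
    rows, cols = linear_sum_assignment(-M)
    joins = []
    for i, j in zip(rows, cols):
        if j < n and S[i, j] > params.join_threshold:
            joins.append((int(i), int(j), float(S[i, j])))
    return joins


def _segment_track_points(seg: Segment) -> list:
    return [TrackPoint(frame=f, x=d.x, y=d.y, radius=d.radius)
            for f, d in seg.points]


def join_segments(segments: Sequence[Segment],
                  params: LinkParams | None = None) -> list:
    """Tier two: chain accepted joins transitively into tracks.

    Unjoined segments become single-segment tracks.  Track ids are assigned
    in order of first frame, then first x coordinate.
    """
    if params is None:
        params = LinkParams()
    segments = list(segments)
    joins = propose_joins(segments, params)
    succ = {i: j for i, j, _ in joins}
    has_pred = {j for _, j, _ in joins}
    chains = []
    for i in range(len(segments)):
        if i in has_pred:
            continue
        chain = [i]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        chains.append(chain)
    tracks = []
    for chain in chains:
        points: list = []
        for idx in chain:
            points.extend(_segment_track_points(segments[idx]))
        tracks.append(points)
    tracks.sort(key=lambda pts: (pts[0].frame, pts[0].x, pts[0].y))
    return [Track(track_id=i, points=pts) for i, pts in enumerate(tracks)]


def filter_short_tracks(tracks: Sequence[Track],
                        params: LinkParams | None = None) -> list:
    """Discard tracks with fewer than ``min_track_len`` points (default 5)."""
    if params is None:
        params = LinkParams()
    return [t for t in tracks if len(t) >= params.min_track_len]


# ---------------------------------------------------------------------------
# Manual track editing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditOp:
    """A manual correction: ('split', track_id, frame) or ('join', id1, id2)."""

    op: str
    a: int
    b: int

    def __post_init__(self) -> None:
        if self.op not in ("split", "join"):
            raise ValueError(f"unknown edit op {self.op!r}")


def edit_tracks(tracks: Sequence[Track], edits: Sequence[EditOp]) -> list:
    """Apply manual corrections: all splits first, then all joins.

    ``split(t, f)`` keeps points with frame ≤ f−1 under the original id and
    moves points with frame ≥ f to a fresh id (max id + 1 at time of split).
    ``join(a, b)`` concatenates b after a (valid only when a ends before b
    starts); the result keeps id a.
    """
    by_id = {t.track_id: list(t.points) for t in tracks}
    if len(by_id) != len(tracks):
        raise ValueError("duplicate track ids")
    for e in edits:
        if e.op != "split":
            continue
        if e.a not in by_id:
            raise ValueError(f"unknown track id {e.a}")
        pts = by_id[e.a]
        head = [p for p in pts if p.frame <= e.b - 1]
        tail = [p for p in pts if p.frame >= e.b]
        if not head or not tail:
            raise ValueError(f"split of track {e.a} at frame {e.b} is empty-sided")
        new_id = max(by_id) + 1
        by_id[e.a] = head
        by_id[new_id] = tail
    for e in edits:
        if e.op != "join":
            continue
        if e.a not in by_id or e.b not in by_id:
            raise ValueError(f"unknown track id in join({e.a}, {e.b})")
        pa, pb = by_id[e.a], by_id[e.b]
        if pa[-1].frame >= pb[0].frame:
            raise ValueError(
                f"join({e.a}, {e.b}): frame ranges overlap "
                f"({pa[-1].frame} >= {pb[0].frame})"
            )
        by_id[e.a] = pa + pb
        del by_id[e.b]
    return [Track(track_id=i, points=pts) for i, pts in sorted(by_id.items())]
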