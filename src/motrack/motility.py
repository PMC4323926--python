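"""Per-step and per-track motility characteristics.

Speeds are in μm/min and always use the actual elapsed time between the two
positions, so frame gaps left by segment joining do not bias them.  The turn
angle is the unsigned angle (degrees, [0, 180]) between successive
displacement vectors.  The arrest coefficient is the fraction of
instantaneous speeds strictly below a threshold (default 0.5 μm/min); the
confinement index is net displacement over path length (1 = perfectly
straight, 0 = closed loop).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .image_io import Calibration
from .tracking import Track

DEFAULT_ARREST_THRESHOLD_UM_MIN = 0.5
_EPS = 1e-12


@dataclass(frozen=True)
class StepMetrics:
    track_id: int
    frame: int                      # frame at the *end* of the step
    speed_um_min: float
    turn_angle_deg: Optional[float] = None


def _displacements_um(track: Track, calibration: Calibration):
    pts = track.points
    px = calibration.pixel_size_um
    vec = np.array([[(b.x - a.x) * px, (b.y - a.y) * px]
                    for a, b in zip(pts, pts[1:])])
    dt_min = np.array([(b.frame - a.frame) * calibration.frame_interval_s / 60.0
                       for a, b in zip(pts, pts[1:])])
    return vec, dt_min


def instantaneous_speeds(track: Track, calibration: Calibration) -> list:
    """One StepMetrics per consecutive point pair; empty for 1-point tracks."""
    if len(track) < 2:
        return []
    vec, dt = _displacements_um(track, calibration)
    dist = np.hypot(vec[:, 0], vec[:, 1])
    return [
        StepMetrics(track.track_id, track.points[i + 1].frame,
                    float(dist[i] / dt[i]))
        for i in range(len(vec))
    ]


def turn_angles(track: Track, calibration: Calibration | None = None) -> list:
    """Angles between successive displacement vectors (needs ≥ 3 points).

    Absent (NaN) when either displacement is zero: a stationary step has no
    direction.
    """
    if len(track) < 3:
        return []
    pts = track.points
    vec = np.array([[b.x - a.x, b.y - a.y] for a, b in zip(pts, pts[1:])])
    out = []
    for i in range(len(vec) - 1):
        v1, v2 = vec[i], vec[i + 1]
        n1, n2 = np.hypot(*v1), np.hypot(*v2)
        if n1 < _EPS or n2 < _EPS:
            angle = float("nan")
        else:
            c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
            angle = float(np.degrees(np.arccos(c)))
        out.append(StepMetrics(track.track_id, pts[i + 1].frame,
                               float("nan"), angle))
    return out


def arrest_coefficient(steps: Sequence[StepMetrics],
                       threshold_um_min: float = DEFAULT_ARREST_THRESHOLD_UM_MIN
                       ) -> Optional[float]:
    """Fraction of instantaneous speeds strictly below the threshold."""
    speeds = [s.speed_um_min for s in steps if np.isfinite(s.speed_um_min)]
    if not speeds:
        return None
    return float(np.mean([v < threshold_um_min for v in speeds]))


def confinement_index(track: Track) -> Optional[float]:
    """Net displacement / total path length, in [0, 1]; None if path is 0."""
    if len(track) < 2:
        return None
    pts = track.points
    path = sum(np.hypot(b.x - a.x, b.y - a.y) for a, b in zip(pts, pts[1:]))
    if path <= 0:
        return None
    net = np.hypot(pts[-1].x - pts[0].x, pts[-1].y - pts[0].y)
    return float(net / path)


def step_table(tracks: Sequence[Track], calibration: Calibration) -> pd.DataFrame:
    """Long per-step table: track_id, frame, speed_um_min, turn_angle_deg."""
    rows = []
    for tr in tracks:
        speeds = {s.frame: s.speed_um_min for s in instantaneous_speeds(tr, calibration)}
        angles = {s.frame: s.turn_angle_deg for s in turn_angles(tr)}
        for f in sorted(speeds):
            rows.append({
                "track_id": tr.track_id, "frame": f,
                "speed_um_min": speeds[f],
                "turn_angle_deg": angles.get(f, float("nan")),
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "speed_um_min",
                                       "turn_angle_deg"])


def summarize_tracks(tracks: Sequence[Track], calibration: Calibration,
                     observations: Sequence | None = None,
                     labels: Sequence | None = None,
                     arrest_threshold_um_min: float = DEFAULT_ARREST_THRESHOLD_UM_MIN
                     ) -> pd.DataFrame:
    """Per-track summary table merging motility, attachment and cell type."""
    from .features import track_attachment

    label_by_id = {l.track_id: l.label for l in labels or []}
    obs_by_id: dict = {}
    for ob in observations or []:
        obs_by_id.setdefault(ob.track_id, []).append(ob)
    known = {t.track_id for t in tracks}
    for tid in list(obs_by_id) + list(label_by_id):
        if tid not in known:
            raise ValueError(f"observation/label references unknown track {tid}")
    attached = track_attachment(observations or [])
    px = calibration.pixel_size_um
    rows = []
    for tr in tracks:
        steps = instantaneous_speeds(tr, calibration)
        speeds = [s.speed_um_min for s in steps]
        angles = [s.turn_angle_deg for s in turn_angles(tr)
                  if s.turn_angle_deg is not None and np.isfinite(s.turn_angle_deg)]
        pts = tr.points
        path = sum(np.hypot(b.x - a.x, b.y - a.y) for a, b in zip(pts, pts[1:])) * px
        net = np.hypot(pts[-1].x - pts[0].x, pts[-1].y - pts[0].y) * px
        obs = obs_by_id.get(tr.track_id, [])
        areas = [o.contact_area_um2 for o in obs if o.contact_area_um2 is not None]
        rows.append({
            "track_id": tr.track_id,
            "n_frames": len(tr),
            "mean_speed_um_min": float(np.mean(speeds)) if speeds else float("nan"),
            "median_turn_angle_deg": float(np.median(angles)) if angles else float("nan"),
            "arrest_coefficient": arrest_coefficient(steps, arrest_threshold_um_min)
            if steps else float("nan"),
            "confinement_index": confinement_index(tr) or float("nan"),
            "path_length_um": float(path),
            "net_displacement_um": float(net),
            "mean_contact_area_um2": float(np.mean(areas)) if areas else float("nan"),
            "attached": attached.get(tr.track_id, False),
            "cell_type": label_by_id.get(tr.track_id, "unassigned"),
        })
    return pd.DataFrame(rows)


SUMMARY_METRICS = ("mean_speed_um_min", "median_turn_angle_deg",
                   "arrest_coefficient", "confinement_index",
                   "path_length_um", "net_displacement_um",
                   "mean_contact_area_um2")


def group_medians(summary: pd.DataFrame, group_col: str,
                  control: str | None = None,
                  metrics: Sequence[str] = SUMMARY_METRICS) -> pd.DataFrame:
    """Population medians of per-track means, per group.

    With ``control`` set, every group's medians are divided by the control
    group's medians (control row becomes all ones) — the heat-map style
    normalisation used for condition comparisons.
    """
    metrics = [m for m in metrics if m in summary.columns]
    med = summary.groupby(group_col)[metrics].median()
    if control is not None:
        if control not in med.index:
            raise ValueError(f"control group {control!r} not present")
        med = med / med.loc[control]
    return med
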