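"""Config-driven end-to-end runs: detect → track → features → metrics."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import motility
from .detection import DetectionParams, detect_cells
from .features import FeatureParams, assign_cell_types, extract_features
from .image_io import (Calibration, ImageSeries, read_image_series,
                       write_overlay_series, write_tracks_table)
from .tracking import (LinkParams, Track, filter_short_tracks, join_segments,
                       link_nearest_neighbor)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    calibration: Calibration
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkParams = field(default_factory=LinkParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    arrest_threshold_um_min: float = motility.DEFAULT_ARREST_THRESHOLD_UM_MIN
    output_dir: Optional[Path] = None
    overlay_channel: Optional[str] = None
    experiment_id: str = "run"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        return cls(
            calibration=Calibration.from_dict(d["calibration"]),
            detection=DetectionParams(**d.get("detection", {})),
            linking=LinkParams(**d.get("linking", {})),
            features=FeatureParams(**d.get("features", {})),
            arrest_threshold_um_min=d.get(
                "arrest_threshold_um_min", motility.DEFAULT_ARREST_THRESHOLD_UM_MIN),
            output_dir=Path(d["output_dir"]) if d.get("output_dir") else None,
            overlay_channel=d.get("overlay_channel"),
            experiment_id=d.get("experiment_id", "run"),
            seed=int(d.get("seed", 0)),
        )

    def effective_parameters(self) -> dict:
        return {
            "calibration": self.calibration.to_dict(),
            "detection": dataclasses.asdict(self.detection),
            "linking": dataclasses.asdict(self.linking),
            "features": dataclasses.asdict(self.features),
            "arrest_threshold_um_min": self.arrest_threshold_um_min,
            "overlay_channel": self.overlay_channel,
            "experiment_id": self.experiment_id,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    config: RunConfig
    detections: list
    tracks: list
    observations: list
    labels: list
    steps: pd.DataFrame
    summary: pd.DataFrame
    log: dict


def load_channels(config: RunConfig) -> dict:
    if "transmitted" not in config.calibration.channels:
        raise PipelineError("io", "missing required channel 'transmitted'")
    channels = {}
    for role, path in config.calibration.channels.items():
        if not Path(path).exists():
            raise PipelineError("io", f"channel {role!r} file not found: {path}")
        channels[role] = read_image_series(path, role, config.calibration)
    shapes = {c.frames.shape for c in channels.values()}
    if len(shapes) > 1:
        raise PipelineError("io", f"channel stacks differ in shape: {sorted(shapes)}")
    return channels


def run_pipeline(config: RunConfig, channels: Optional[dict] = None
                 ) -> PipelineResult:
    """Run detect → track → features → metrics; write outputs if configured.

    ``channels`` may be passed directly (role → ImageSeries) to skip file
    I/O; otherwise they are read from the calibration's channel paths.
    """
    log: dict = {"parameters": config.effective_parameters(), "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        def done(**counts):
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3),
                                   **counts}
        return done

    if channels is None:
        done = stage("io")
        channels = load_channels(config)
        done(n_channels=len(channels))
    if "transmitted" not in channels:
        raise PipelineError("io", "missing required channel 'transmitted'")

    done = stage("detection")
    detections = detect_cells(channels["transmitted"], config.detection)
    n_frames = channels["transmitted"].n_frames
    done(n_detections=len(detections),
         detections_per_frame=round(len(detections) / max(n_frames, 1), 2))

    done = stage("tracking")
    segments = link_nearest_neighbor(detections, config.linking)
    joined = join_segments(segments, config.linking)
    tracks = filter_short_tracks(joined, config.linking)
    done(n_segments=len(segments), joins_accepted=len(segments) - len(joined),
         n_tracks=len(tracks))

    done = stage("features")
    secondary = {r: s for r, s in channels.items()}
    observations = extract_features(tracks, secondary, config.calibration,
                                    config.detection, config.features)
    obs_by_track: dict = {}
    for ob in observations:
        obs_by_track.setdefault(ob.track_id, []).append(ob)
    labels = assign_cell_types(obs_by_track, config.features.ratio_high,
                               config.features.ratio_low)
    done(n_observations=len(observations))

    done = stage("metrics")
    steps = motility.step_table(tracks, config.calibration)
    summary = motility.summarize_tracks(
        tracks, config.calibration, observations, labels,
        arrest_threshold_um_min=config.arrest_threshold_um_min)
    summary.insert(0, "experiment_id", config.experiment_id)
    done(n_tracks_summarised=len(summary))

    result = PipelineResult(config=config, detections=detections, tracks=tracks,
                            observations=observations, labels=labels,
                            steps=steps, summary=summary, log=log)
    if config.output_dir is not None:
        write_outputs(result, channels)
    return result


def write_outputs(result: PipelineResult, channels: dict) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(d) for d in result.detections]).to_csv(
        out / "detections.csv", index=False)
    write_tracks_table(result.tracks, result.observations,
                       result.config.calibration, out / "tracks.csv")
    result.steps.to_csv(out / "steps.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    (out / "run_log.json").write_text(json.dumps(result.log, indent=2))
    role = result.config.overlay_channel
    if role:
        if role not in channels:
            raise PipelineError("overlay", f"unknown overlay channel {role!r}")
        outlines: dict = {}
        for ob in result.observations:
            if role in ob.outlines:
                outlines.setdefault(ob.frame, []).append(ob.outlines[role])
        write_overlay_series(channels[role], outlines, out / f"overlay_{role}.tif")


def run_batch(configs: Sequence[RunConfig]) -> tuple:
    """Independent runs; one failure does not abort the rest.

    Returns (results dict by experiment_id, combined summary table, failures).
    """
    if not configs:
        raise ValueError("run_batch needs at least one config")
    results: dict = {}
    failures: dict = {}
    summaries = []
    for cfg in configs:
        try:
            res = run_pipeline(cfg)
            results[cfg.experiment_id] = res
            summaries.append(res.summary)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            failures[cfg.experiment_id] = str(exc)
    combined = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    return results, combined, failures


def preview_detection(config: RunConfig, frame_index: int,
                      channels: Optional[dict] = None, outdir=None) -> dict:
    """Write/return the detection stage images for one frame.

    Returns dict with 'edges', 'accumulator', 'overlay' arrays; when
    ``outdir`` is given they are also written as TIFFs.
    """
    from skimage.draw import disk as draw_disk
    from skimage.transform import rescale

    from .detection import (circular_hough, compute_edge_map, gradient_field,
                            select_centroids)
    from .image_io import write_image_series

    if channels is None:
        channels = load_channels(config)
    series = channels["transmitted"]
    if not (0 <= frame_index < series.n_frames):
        raise PipelineError("preview", f"frame {frame_index} out of range "
                                       f"(0..{series.n_frames - 1})")
    params = config.detection
    frame = np.asarray(series.frames[frame_index], dtype=float)
    s = params.scale_factor
    work = rescale(frame, s, order=1, anti_aliasing=s < 1,
                   preserve_range=True) if s != 1.0 else frame
    edges = compute_edge_map(work, params)
    acc, votes = circular_hough(edges, gradient_field(work, params.canny_sigma),
                                params, return_radius_votes=True)
    dets = select_centroids(acc, params, radius_votes=votes, frame=frame_index)
    overlay = frame.copy()
    marker = float(frame.max())
    for d in dets:
        rr, cc = draw_disk((d.y / s, d.x / s), max(2.0, d.radius / s / 4),
                           shape=frame.shape)
        overlay[rr, cc] = marker
    out = {"edges": edges.astype(np.uint8), "accumulator": acc,
           "overlay": overlay, "detections": dets}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_image_series(out["edges"][None].astype(np.uint8) * 255,
                           outdir / "preview_edges.tif")
        write_image_series(acc[None].astype(np.float32),
                           outdir / "preview_accumulator.tif")
        write_image_series(overlay[None].astype(np.float32),
                           outdir / "preview_overlay.tif")
    return out
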