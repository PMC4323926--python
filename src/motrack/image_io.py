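"""Reading and writing of image series, ground truth and tabular results.

All coordinates are 0-based pixels with ``x`` the column index and ``y`` the
row index (origin at the top-left corner).  Conversion to physical units
multiplies by the pixel size in micrometres.  Frame indices are 0-based
everywhere inside this package; the ViPER XML dialect on disk is 1-based and
is normalised on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from lxml import etree

CHANNEL_ROLES = ("transmitted", "reflection", "fluor1", "fluor2")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class Calibration:
    """Spatial/temporal calibration plus the channel-role → file mapping."""

    pixel_size_um: float
    frame_interval_s: float
    channels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if len(self.channels) > 4:
            raise ValueError("at most 4 channels supported")

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channels": {k: str(v) for k, v in self.channels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Calibration":
        return cls(
            pixel_size_um=float(d["pixel_size_um"]),
            frame_interval_s=float(d["frame_interval_s"]),
            channels=dict(d.get("channels", {})),
        )


@dataclass
class ImageSeries:
    """One channel's frame stack with calibration.

    ``frames`` is an (n_frames, height, width) array.  All channels of an
    experiment are assumed co-registered, so tracking results from the
    transmitted channel can index secondary channels directly.
    """

    frames: np.ndarray
    channel_role: str
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, h, w) stack")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.channel_role!r}")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box: top-left corner (x, y), extents (w, h)."""

    frame: int
    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extents must be positive")

    @property
    def center(self) -> tuple:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass
class GroundTruthTrack:
    """An annotated object: per-frame bounding boxes keyed by frame index."""

    gt_id: int
    boxes: dict

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValueError("ground-truth track needs at least one box")

    @property
    def frames(self) -> list:
        return sorted(self.boxes)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    # multi-sample pixels (RGB etc.) are collapsed by channel mean
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return arr.mean(axis=-1)
    return arr


def read_image_series(path, role: str, calibration: Calibration) -> ImageSeries:
    """Load a multi-page TIFF or a directory of per-frame TIFFs.

    Per-frame files are ordered by lexicographic filename.  RGB(A) pages are
    converted to grayscale by channel mean.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF files in directory {path}")
        frames = [_to_grayscale(tifffile.imread(f)) for f in files]
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - tifffile error text varies
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        arr = np.asarray(arr)
        if arr.ndim == 2:
            frames = [arr]
        elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            frames = [_to_grayscale(arr)]
        elif arr.ndim == 3:
            frames = list(arr)
        elif arr.ndim == 4:
            frames = [_to_grayscale(a) for a in arr]
        else:
            raise FormatError(f"unsupported TIFF dimensionality {arr.shape}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
    return ImageSeries(
        frames=np.stack(frames),
        channel_role=role,
        pixel_size_um=calibration.pixel_size_um,
        frame_interval_s=calibration.frame_interval_s,
    )


def write_image_series(frames: np.ndarray, path) -> None:
    """Write an (n, h, w) stack as a multi-page float32/native TIFF."""
    frames = np.asarray(frames)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if frames.dtype == np.float64:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")


# ---------------------------------------------------------------------------
# ViPER-dialect ground truth (object → bbox subset; on-disk frames 1-based)
# ---------------------------------------------------------------------------

def _parse_framespan(span: str) -> tuple:
    a, b = span.split(":")
    return int(a), int(b)


def read_viper_ground_truth(path) -> list:
    """Parse the bbox subset of a ViPER XML annotation file.

    Returns one :class:`GroundTruthTrack` per annotated object, with frame
    indices normalised to 0-based.  Non-bbox descriptors are ignored.
    """
    tree = etree.parse(str(path))
    tracks = []
    for obj in tree.iter():
        if etree.QName(obj).localname != "object":
            continue
        obj_id = obj.get("id")
        boxes = {}
        for el in obj.iter():
            if etree.QName(el).localname != "bbox":
                continue
            try:
                span = el.get("framespan")
                x = float(el.get("x"))
                y = float(el.get("y"))
                w = float(el.get("width"))
                h = float(el.get("height"))
                f0, f1 = _parse_framespan(span)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"malformed bbox attributes in object id={obj_id}"
                ) from exc
            for f in range(f0, f1 + 1):
                boxes[f - 1] = BoundingBox(frame=f - 1, x=x, y=y, w=w, h=h)
        if boxes:
            tracks.append(GroundTruthTrack(gt_id=int(obj_id), boxes=boxes))
    return tracks


def write_viper_ground_truth(tracks: Sequence[GroundTruthTrack], path,
                             sourcefile: str = "synthetic") -> None:
    """Write tracks in the minimal ViPER bbox dialect (1-based frames)."""
    root = etree.Element("viper")
    data = etree.SubElement(root, "data")
    src = etree.SubElement(data, "sourcefile", filename=sourcefile)
    for tr in tracks:
        frames = tr.frames
        obj = etree.SubElement(
            src, "object", name="CELL", id=str(tr.gt_id),
            framespan=f"{frames[0] + 1}:{frames[-1] + 1}",
        )
        attr = etree.SubElement(obj, "attribute", name="bbox")
        for f in frames:
            b = tr.boxes[f]
            etree.SubElement(
                attr, "bbox",
                framespan=f"{f + 1}:{f + 1}",
                x=repr(float(b.x)), y=repr(float(b.y)),
                width=repr(float(b.w)), height=repr(float(b.h)),
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = (
    "contact_area_um2", "attached", "mean_fluor1", "mean_fluor2", "aspect_ratio",
)


def write_tracks_table(tracks, observations, calibration: Calibration, path) -> None:
    """Write the long-format positions+features table (UTF-8 CSV).

    One row per track position: track_id, frame, time_s, x_um, y_um,
    radius_px, then one column per extracted feature (empty where absent).
    A sidecar JSON next to the CSV stores the calibration.
    """
    obs_index = {}
    track_frames = {t.track_id: {p.frame for p in t.points} for t in tracks}
    for ob in observations or []:
        if ob.track_id not in track_frames or ob.frame not in track_frames[ob.track_id]:
            raise ValueError(
                f"observation references unknown (track {ob.track_id}, frame {ob.frame})"
            )
        obs_index[(ob.track_id, ob.frame)] = ob
    rows = []
    px = calibration.pixel_size_um
    for t in tracks:
        for p in t.points:
            row = {
                "track_id": t.track_id,
                "frame": p.frame,
                "time_s": p.frame * calibration.frame_interval_s,
                "x_um": p.x * px,
                "y_um": p.y * px,
                "radius_px": p.radius,
            }
            ob = obs_index.get((t.track_id, p.frame))
            for col in FEATURE_COLUMNS:
                row[col] = getattr(ob, col, None) if ob is not None else None
            rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".calibration.json")
    sidecar.write_text(json.dumps(calibration.to_dict(), indent=2))


def read_tracks_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_overlay_series(series: ImageSeries, outlines, path,
                         marker_value: float | None = None) -> None:
    """Burn cell outlines into a copy of the series and write it as TIFF.

    ``outlines`` maps frame index → iterable of (N, 2) arrays of (x, y)
    polygon vertices in global pixel coordinates.  Outline pixels are set to
    a fixed marker value (default: the series maximum).
    """
    from skimage.draw import polygon_perimeter

    out = np.array(series.frames, copy=True)
    if marker_value is None:
        marker_value = float(out.max())
    h, w = out.shape[1:]
    for f, polys in (outlines or {}).items():
        for poly in polys:
            poly = np.asarray(poly, dtype=float)
            if len(poly) < 2:
                continue
            rr, cc = polygon_perimeter(
                np.clip(poly[:, 1], 0, h - 1),
                np.clip(poly[:, 0], 0, w - 1),
                shape=(h, w),
            )
            out[f, rr, cc] = marker_value
    write_image_series(out, path)
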