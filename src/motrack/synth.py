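"""Synthetic multi-channel T-cell motility movies with exhaustive ground truth.

The generator emulates the phenomenology of chemokinesis assays imaged in
four co-registered channels:

* **transmitted**: roughly circular, partially polarised cells drawn as
  soft-edged ellipses on a mid-gray background, giving the edge contrast the
  detector consumes (no attempt at real DIC shading physics);
* **reflection (IRM)**: dark irregular contact footprints under an attached
  subset of cells, on a background with slow spatiotemporal intensity drift
  (the property that defeats global thresholding on real IRM data);
* **fluor1/fluor2**: disk-like fluorescence at per-population vital-dye
  intensities, so two mixed populations can be told apart.

Motion is a persistent random walk with an inverse speed–turn coupling:
per-step speeds are log-normal around the population mean, and the heading
increment's standard deviation shrinks for fast steps (cells alternate
between moving straight and turning while slow).  Boundaries are reflective
and cells softly repel below a contact distance, so at default density they
never overlap.

Default parameters reproduce a chemokinesis acquisition: 0.439 μm pixels,
33.3 s frame interval, a 512 px (≈ 225 μm) square field, and two equal
dye-labelled populations with mean speeds 5 and 10 μm/min.  Everything is
driven by a single integer seed; identical seed and parameters give
bit-identical movies and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .image_io import (BoundingBox, Calibration, GroundTruthTrack, ImageSeries,
                       write_image_series, write_viper_ground_truth)

POPULATIONS = ("typeA", "typeB")


@dataclass(frozen=True)
class SynthParams:
    n_cells: int = 30
    field_size_px: int = 512
    n_frames: int = 50
    pixel_size_um: float = 0.439
    frame_interval_s: float = 33.3
    # motion (per population: typeA, typeB)
    speed_mean_um_min: tuple = (5.0, 10.0)
    speed_sd_um_min: tuple = (1.5, 2.0)
    turn_concentration: float = 4.0       # persistence; heading sd = 1/sqrt(k)
    speed_turn_coupling: float = -1.0     # <= 0; inverse speed–turn relation
    population_fraction: float = 0.5      # fraction of cells in typeA
    # morphology & attachment
    cell_radius_um: float = 4.0
    cell_radius_sd_um: float = 0.3
    aspect_max: float = 1.9               # degree of morphological polarisation
    attach_fraction: float = 0.5
    footprint_area_um2_mean: float = 25.0
    footprint_area_um2_sd: float = 5.0
    # rendering
    dye_intensity: tuple = ((0.8, 0.1), (0.1, 0.8))  # (fluor1, fluor2) per pop
    transmitted_background: float = 0.5
    transmitted_amplitude: float = 0.12
    reflection_background: float = 0.5
    reflection_footprint: float = 0.15
    reflection_drift_amplitude: float = 0.04
    fluor_background: float = 0.05
    noise_sd: float = 0.03
    # placement
    min_separation_px: float = 36.0       # initial spacing (easy mode)
    contact_distance_px: float = 26.0     # soft-repulsion distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_frames < 1 or self.field_size_px < 32:
            raise ValueError("invalid field/frame/cell counts")
        if not (0 <= self.attach_fraction <= 1):
            raise ValueError("attach_fraction must be in [0, 1]")
        if not (0 <= self.population_fraction <= 1):
            raise ValueError("population_fraction must be in [0, 1]")
        if self.speed_turn_coupling > 0:
            raise ValueError("speed_turn_coupling must be <= 0")
        if self.turn_concentration < 0:
            raise ValueError("turn_concentration must be >= 0")

    @property
    def calibration(self) -> Calibration:
        return Calibration(pixel_size_um=self.pixel_size_um,
                           frame_interval_s=self.frame_interval_s)

    @property
    def px_per_step_per_um_min(self) -> float:
        """Pixels moved per frame by a cell at 1 μm/min."""
        return self.frame_interval_s / 60.0 / self.pixel_size_um


@dataclass
class SynthTruth:
    """Everything the generator knows about the movie it produced."""

    params: SynthParams
    cell_type: list                      # per cell, "typeA"/"typeB"
    attached: np.ndarray                 # (n,) bool
    radius_px: np.ndarray                # (n,)
    dye: np.ndarray                      # (n, 2) fluor intensities
    positions: np.ndarray                # (n, T, 2) px, (x, y)
    speeds_um_min: np.ndarray            # (n, T-1) programmed step speeds
    headings: np.ndarray                 # (n, T)
    aspect: np.ndarray                   # (n, T) drawn aspect ratio
    footprint_r0_px: np.ndarray          # (n,) base footprint radius
    footprint_coeffs: np.ndarray         # (n, 3) boundary modulation amplitudes
    footprint_phases: np.ndarray         # (n, 3)
    footprint_offset: np.ndarray         # (n, T, 2) footprint centre jitter
    contact_area_px: Optional[np.ndarray] = None   # (n, T), filled by render

    @property
    def n_cells(self) -> int:
        return len(self.cell_type)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def ellipse_axes(self, i: int, t: int) -> tuple:
        """Semi-axes (a, b) of cell i's ellipse at frame t (area kept π·r²)."""
        r = self.radius_px[i]
        ar = self.aspect[i, t]
        return r * np.sqrt(ar), r / np.sqrt(ar)

    def bounding_box(self, i: int, t: int) -> BoundingBox:
        a, b = self.ellipse_axes(i, t)
        phi = self.headings[i, t]
        hw = np.hypot(a * np.cos(phi), b * np.sin(phi))
        hh = np.hypot(a * np.sin(phi), b * np.cos(phi))
        cx, cy = self.positions[i, t]
        return BoundingBox(frame=t, x=cx - hw, y=cy - hh, w=2 * hw, h=2 * hh)

    def ground_truth_tracks(self) -> list:
        return [
            GroundTruthTrack(
                gt_id=i,
                boxes={t: self.bounding_box(i, t) for t in range(self.n_frames)},
            )
            for i in range(self.n_cells)
        ]

    def cell_outline(self, i: int, t: int, n_vertices: int = 32) -> np.ndarray:
        """(N, 2) polygon of the drawn transmitted-channel ellipse."""
        a, b = self.ellipse_axes(i, t)
        phi = self.headings[i, t]
        th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        ex, ey = a * np.cos(th), b * np.sin(th)
        x = self.positions[i, t, 0] + ex * np.cos(phi) - ey * np.sin(phi)
        y = self.positions[i, t, 1] + ex * np.sin(phi) + ey * np.cos(phi)
        return np.column_stack([x, y])

    def feature_records(self) -> dict:
        """Per-frame ground-truth feature records for evaluation.

        Contact area requires a rendered movie (realised pixel areas).
        """
        px2 = self.params.pixel_size_um ** 2
        out: dict = {}
        for t in range(self.n_frames):
            recs = []
            for i in range(self.n_cells):
                area = (float(self.contact_area_px[i, t]) * px2
                        if self.contact_area_px is not None and self.attached[i]
                        else 0.0)
                recs.append({
                    "id": i,
                    "x": float(self.positions[i, t, 0]),
                    "y": float(self.positions[i, t, 1]),
                    "cell_type": self.cell_type[i],
                    "attached": bool(self.attached[i]),
                    "contact_area_um2": area,
                    "mean_fluor1": float(self.dye[i, 0]),
                    "mean_fluor2": float(self.dye[i, 1]),
                    "aspect_ratio": float(self.aspect[i, t]),
                })
            out[t] = recs
        return out

    def features_table(self) -> pd.DataFrame:
        rows = []
        for t, recs in self.feature_records().items():
            for r in recs:
                rows.append({"frame": t, "cell_id": r["id"], **{
                    k: v for k, v in r.items() if k != "id"}})
        return pd.DataFrame(rows)


def _initial_positions(rng, params: SynthParams) -> np.ndarray:
    margin = params.cell_radius_um / params.pixel_size_um + 4
    lo, hi = margin, params.field_size_px - margin
    pos = []
    attempts = 0
    while len(pos) < params.n_cells:
        p = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(p - q)) >= params.min_separation_px for q in pos):
            pos.append(p)
        attempts += 1
        if attempts > 20000 * max(params.n_cells, 1):
            raise RuntimeError("cannot place cells at requested density; "
                               "lower n_cells or min_separation_px")
    return np.array(pos) if pos else np.empty((0, 2))


def simulate_tracks(params: SynthParams | None = None) -> SynthTruth:
    """Simulate cell states and trajectories (no rendering).

    Persistent random walk: per-step speed is log-normal around the cell's
    population mean; the heading increment is normal with standard deviation
    ``exp(coupling · (s − μ)/μ) / sqrt(turn_concentration)``, so with
    negative coupling fast steps turn less.  Boundaries reflect and cells
    closer than ``contact_distance_px`` are pushed apart symmetrically.
    """
    if params is None:
        params = SynthParams()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    n, T = params.n_cells, params.n_frames
    pop_idx = (rng.random(n) >= params.population_fraction).astype(int)
    cell_type = [POPULATIONS[k] for k in pop_idx]
    attached = rng.random(n) < params.attach_fraction
    radius_px = np.clip(
        rng.normal(params.cell_radius_um, params.cell_radius_sd_um, n),
        1.5, None) / params.pixel_size_um
    dye = np.array([params.dye_intensity[k] for k in pop_idx], dtype=float)

    positions = np.zeros((n, T, 2))
    if n:
        positions[:, 0] = _initial_positions(rng, params)
    headings = np.zeros((n, T))
    headings[:, 0] = rng.uniform(0, 2 * np.pi, n)
    aspect = np.zeros((n, T))
    ar_hi = params.aspect_max
    aspect[:, 0] = rng.uniform(1.0 + 0.2 * (ar_hi - 1), 1.0 + 0.7 * (ar_hi - 1), n)
    speeds = np.zeros((n, max(T - 1, 0)))

    mu = np.array([params.speed_mean_um_min[k] for k in pop_idx], dtype=float)
    sd = np.array([params.speed_sd_um_min[k] for k in pop_idx], dtype=float)
    # log-normal with arithmetic mean mu and sd sd
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_log = np.sqrt(np.log1p((sd / mu) ** 2)) if n else np.empty(0)
        mu_log = np.log(mu) - sigma_log ** 2 / 2 if n else np.empty(0)
    base_turn_sd = (1.0 / np.sqrt(params.turn_concentration)
                    if params.turn_concentration > 0 else np.inf)
    margin = params.cell_radius_um / params.pixel_size_um + 3
    lo, hi = margin, params.field_size_px - margin
    step_scale = params.px_per_step_per_um_min

    for t in range(1, T):
        s = np.exp(mu_log + sigma_log * rng.standard_normal(n)) if n else np.empty(0)
        speeds[:, t - 1] = s
        if np.isfinite(base_turn_sd):
            turn_sd = base_turn_sd * np.exp(
                params.speed_turn_coupling * (s - mu) / mu)
            dtheta = rng.normal(0.0, 1.0, n) * turn_sd
        else:
            dtheta = np.zeros(n)
        headings[:, t] = headings[:, t - 1] + dtheta
        step = s * step_scale
        positions[:, t, 0] = positions[:, t - 1, 0] + step * np.cos(headings[:, t])
        positions[:, t, 1] = positions[:, t - 1, 1] + step * np.sin(headings[:, t])
        # soft pairwise repulsion keeps cells from overlapping
        for _ in range(4):
            moved = False
            for i in range(n):
                for j in range(i + 1, n):
                    dvec = positions[j, t] - positions[i, t]
                    d = np.hypot(*dvec)
                    if d < params.contact_distance_px:
                        push = (params.contact_distance_px - d) / 2 + 0.1
                        u = dvec / d if d > 1e-9 else np.array([1.0, 0.0])
                        positions[i, t] -= u * push
                        positions[j, t] += u * push
                        moved = True
            if not moved:
                break
        # reflective boundaries
        for ax in (0, 1):
            over = positions[:, t, ax] > hi
            under = positions[:, t, ax] < lo
            positions[over, t, ax] = 2 * hi - positions[over, t, ax]
            positions[under, t, ax] = 2 * lo - positions[under, t, ax]
            if over.any() or under.any():
                flip = over | under
                if ax == 0:
                    headings[flip, t] = np.pi - headings[flip, t]
                else:
                    headings[flip, t] = -headings[flip, t]
        aspect[:, t] = np.clip(aspect[:, t - 1] + rng.normal(0, 0.05, n),
                               1.0, params.aspect_max)

    area_px2 = np.clip(
        rng.normal(params.footprint_area_um2_mean, params.footprint_area_um2_sd, n),
        params.footprint_area_um2_mean * 0.3, None) / params.pixel_size_um ** 2
    coeffs = rng.normal(0.0, 0.08, (n, 3))
    phases = rng.uniform(0, 2 * np.pi, (n, 3))
    # base radius giving the target area for the modulated boundary
    r0 = np.sqrt(area_px2 / (np.pi * (1 + 0.5 * (coeffs ** 2).sum(axis=1))))
    offset = rng.normal(0, 1.0, (n, T, 2))

    return SynthTruth(
        params=params, cell_type=cell_type, attached=attached,
        radius_px=radius_px, dye=dye, positions=positions,
        speeds_um_min=speeds, headings=headings, aspect=aspect,
        footprint_r0_px=r0, footprint_coeffs=coeffs, footprint_phases=phases,
        footprint_offset=offset,
    )


def _ellipse_soft_mask(shape, cx, cy, a, b, phi, patch_pad=3):
    """(slice_y, slice_x, soft, hard) for an ellipse drawn on a patch."""
    h, w = shape
    ext = max(a, b) + patch_pad
    x0, x1 = int(max(0, np.floor(cx - ext))), int(min(w, np.ceil(cx + ext) + 1))
    y0, y1 = int(max(0, np.floor(cy - ext))), int(min(h, np.ceil(cy + ext) + 1))
    if x0 >= x1 or y0 >= y1:
        return None
    X, Y = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    dx, dy = X - cx, Y - cy
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    r_eff = np.sqrt(a * b)
    soft = np.clip((1.0 - q) * r_eff + 0.5, 0.0, 1.0)
    return slice(y0, y1), slice(x0, x1), soft, q <= 1.0


def _footprint_mask(shape, cx, cy, r0, coeffs, phases):
    h, w = shape
    rmax = r0 * (1 + np.abs(coeffs).sum()) + 2
    x0, x1 = int(max(0, np.floor(cx - rmax))), int(min(w, np.ceil(cx + rmax) + 1))
    y0, y1 = int(max(0, np.floor(cy - rmax))), int(min(h, np.ceil(cy + rmax) + 1))
    if x0 >= x1 or y0 >= y1:
        return None
    X, Y = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    dx, dy = X - cx, Y - cy
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    rb = r0 * (1 + sum(c * np.cos((k + 2) * theta + p)
                       for k, (c, p) in enumerate(zip(coeffs, phases))))
    return slice(y0, y1), slice(x0, x1), rho <= rb


def render_movie(truth: SynthTruth, params: SynthParams | None = None) -> dict:
    """Render all four channels; fills ``truth.contact_area_px``.

    Returns a dict of channel role → :class:`ImageSeries`.  Gaussian noise of
    ``noise_sd`` is added everywhere; the reflection background drifts slowly
    in space and time.
    """
    if params is None:
        params = truth.params
    n, T = truth.n_cells, truth.n_frames
    hw = (params.field_size_px, params.field_size_px)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    trans = np.zeros((T,) + hw, dtype=np.float32)
    refl = np.zeros((T,) + hw, dtype=np.float32)
    fl1 = np.zeros((T,) + hw, dtype=np.float32)
    fl2 = np.zeros((T,) + hw, dtype=np.float32)
    truth.contact_area_px = np.zeros((n, T))

    yy = np.arange(hw[0])[:, None]
    xx = np.arange(hw[1])[None, :]
    for t in range(T):
        trans_f = np.full(hw, params.transmitted_background, dtype=float)
        drift = params.reflection_drift_amplitude * (
            np.sin(2 * np.pi * xx / 220.0 + 0.11 * t)
            * np.cos(2 * np.pi * yy / 180.0 - 0.07 * t))
        refl_f = params.reflection_background + drift
        fl1_f = np.full(hw, params.fluor_background, dtype=float)
        fl2_f = np.full(hw, params.fluor_background, dtype=float)
        for i in range(n):
            cx, cy = truth.positions[i, t]
            a, b = truth.ellipse_axes(i, t)
            phi = truth.headings[i, t]
            res = _ellipse_soft_mask(hw, cx, cy, a, b, phi)
            if res is not None:
                sy, sx, soft, _ = res
                trans_f[sy, sx] += params.transmitted_amplitude * soft
            r = truth.radius_px[i]
            disk = _ellipse_soft_mask(hw, cx, cy, r, r, 0.0)
            if disk is not None:
                sy, sx, _, hard = disk
                if truth.dye[i, 0] > 0:
                    fl1_f[sy, sx][hard] = truth.dye[i, 0]
                if truth.dye[i, 1] > 0:
                    fl2_f[sy, sx][hard] = truth.dye[i, 1]
            if truth.attached[i]:
                fx = cx + truth.footprint_offset[i, t, 0]
                fy = cy + truth.footprint_offset[i, t, 1]
                fp = _footprint_mask(hw, fx, fy, truth.footprint_r0_px[i],
                                     truth.footprint_coeffs[i],
                                     truth.footprint_phases[i])
                if fp is not None:
                    sy, sx, hard = fp
                    refl_f[sy, sx][hard] = params.reflection_footprint
                    truth.contact_area_px[i, t] = float(hard.sum())
        trans[t] = trans_f + rng.normal(0, params.noise_sd, hw)
        refl[t] = refl_f + rng.normal(0, params.noise_sd, hw)
        fl1[t] = fl1_f + rng.normal(0, params.noise_sd, hw)
        fl2[t] = fl2_f + rng.normal(0, params.noise_sd, hw)

    def series(arr, role):
        return ImageSeries(frames=arr, channel_role=role,
                           pixel_size_um=params.pixel_size_um,
                           frame_interval_s=params.frame_interval_s)

    return {
        "transmitted": series(trans, "transmitted"),
        "reflection": series(refl, "reflection"),
        "fluor1": series(fl1, "fluor1"),
        "fluor2": series(fl2, "fluor2"),
    }


def generate_movie(params: SynthParams | None = None) -> tuple:
    """Convenience: simulate + render.  Returns (truth, channels dict)."""
    truth = simulate_tracks(params)
    channels = render_movie(truth)
    return truth, channels


def export_truth(truth: SynthTruth, outdir) -> dict:
    """Write ground truth to ``outdir``: ViPER XML boxes, outline ROI lists
    (JSON), feature CSV and a parameter echo.  Returns the paths."""
    import json
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "viper_xml": outdir / "ground_truth.xml",
        "features_csv": outdir / "ground_truth_features.csv",
        "outlines_json": outdir / "ground_truth_outlines.json",
        "params_json": outdir / "synth_params.json",
    }
    write_viper_ground_truth(truth.ground_truth_tracks(), paths["viper_xml"])
    truth.features_table().to_csv(paths["features_csv"], index=False)
    outlines = {
        str(t): {str(i): truth.cell_outline(i, t).round(3).tolist()
                 for i in range(truth.n_cells)}
        for t in range(truth.n_frames)
    }
    paths["outlines_json"].write_text(json.dumps(outlines))
    paths["params_json"].write_text(json.dumps(asdict(truth.params), indent=2))
    return paths


def export_movie(channels: dict, outdir) -> dict:
    """Write each channel as a multi-page float32 TIFF; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for role, series in channels.items():
        p = outdir / f"{role}.tif"
        write_image_series(series.frames, p)
        paths[role] = p
    return paths
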