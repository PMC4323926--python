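"""Cell detection in transmitted-light frames.

The detector is a two-step hybrid: a Canny edge filter produces a thin binary
edge map, and a gradient-directed circular Hough transform (CHT) votes over a
radius range to build an accumulator whose local maxima are cell centroids.
Working on edges makes detection robust to the low-contrast, partially drawn
boundaries typical of DIC/phase-contrast images of crowded T cells: a circle
can be recovered from a non-contiguous, partial set of edge pixels.

Frames may be resampled by ``scale_factor`` before detection so that cell
radii fall inside the default voting radius range; detected centroids are
mapped back to original-image coordinates afterwards.

Hysteresis thresholds are expressed as fractions of the maximum gradient
magnitude of the (min-max normalised) frame, which makes the edge map — and
hence the detection count — invariant under uniform additive or
multiplicative intensity changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.transform import rescale


@dataclass(frozen=True)
class DetectionParams:
    """Detection stage parameters.

    Defaults assume the reference scale where cell radii are ≈ 8–15 px after
    resampling; ``scale_factor`` adapts other magnifications to that range.
    """

    canny_sigma: float = 2.0          # Gaussian pre-smoothing, px
    canny_low: float = 0.1            # hysteresis low, fraction of max gradient
    canny_high: float = 0.25          # hysteresis high, fraction of max gradient
    radius_min: int = 6               # CHT voting radius range, px (scaled image)
    radius_max: int = 18
    accumulator_sigma: float = 2.0    # post-vote smoothing, px
    vote_fraction: float = 0.35       # accept maxima ≥ vote_fraction × global max
    # suppression radius for maxima of imperfect (elongated) circles, px:
    # a polarised cell's vote ridge can split into two maxima up to about
    # 1.5 cell radii apart, so suppression must reach the radius range's top
    maxima_min_separation: float = 18.0
    scale_factor: float = 1.0         # resampling applied before detection

    def __post_init__(self) -> None:
        if self.canny_sigma <= 0:
            raise ValueError("canny_sigma must be positive")
        if not (0 <= self.canny_low < self.canny_high < 1):
            raise ValueError("need 0 <= canny_low < canny_high < 1")
        if self.radius_min < 1 or self.radius_max <= self.radius_min:
            raise ValueError("need 1 <= radius_min < radius_max")
        if self.accumulator_sigma < 0:
            raise ValueError("accumulator_sigma must be >= 0")
        if not (0 < self.vote_fraction <= 1):
            raise ValueError("vote_fraction must be in (0, 1]")
        if self.maxima_min_separation <= 0 or self.scale_factor <= 0:
            raise ValueError("maxima_min_separation and scale_factor must be positive")

    @property
    def radii(self) -> np.ndarray:
        return np.arange(self.radius_min, self.radius_max + 1)


@dataclass(frozen=True)
class Detection:
    """A per-frame cell hypothesis in original (unscaled) pixel coordinates."""

    frame: int
    x: float
    y: float
    radius: float
    score: float


def _normalize(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    lo, hi = frame.min(), frame.max()
    if hi <= lo:
        return np.zeros_like(frame)
    return (frame - lo) / (hi - lo)


def gradient_field(frame: np.ndarray, sigma: float) -> tuple:
    """(gy, gx) Sobel gradients of the Gaussian-smoothed normalised frame.

    Matches the gradient used inside :func:`skimage.feature.canny` so the
    relative hysteresis thresholds refer to the same magnitude scale.
    """
    smoothed = ndi.gaussian_filter(_normalize(frame), sigma)
    return ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1)


def compute_edge_map(frame: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Binary edge map via Canny with thresholds relative to the max gradient.

    A constant frame has no gradient and yields an all-zero map.
    """
    norm = _normalize(frame)
    gy, gx = gradient_field(frame, params.canny_sigma)
    gmax = float(np.hypot(gy, gx).max())
    if gmax == 0:
        return np.zeros(norm.shape, dtype=bool)
    return canny(
        norm,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low * gmax,
        high_threshold=params.canny_high * gmax,
    )


def circular_hough(edges: np.ndarray, gradient: tuple, params: DetectionParams,
                   return_radius_votes: bool = False):
    """Gradient-directed circular Hough voting over a radius range.

    Each edge pixel casts one vote per radius in ``[radius_min, radius_max]``
    at the two points offset along ± its local gradient direction (a cell
    boundary's gradient points toward or away from the centre depending on
    contrast polarity).  The per-radius vote stacks are summed into a single
    2D accumulator, then smoothed with ``accumulator_sigma`` so that votes
    from imperfectly circular cells coalesce into one maximum.

    Returns the smoothed 2D accumulator; with ``return_radius_votes=True``
    also returns the raw (n_radii, h, w) vote stack used for radius
    estimation.
    """
    edges = np.asarray(edges, dtype=bool)
    gy, gx = gradient
    if gy.shape != edges.shape or gx.shape != edges.shape:
        raise ValueError("edges and gradient must share shape")
    h, w = edges.shape
    radii = params.radii
    votes = np.zeros((len(radii), h, w), dtype=np.float32)
    ys, xs = np.nonzero(edges)
    if len(ys):
        g_y = gy[ys, xs]
        g_x = gx[ys, xs]
        norm = np.hypot(g_y, g_x)
        ok = norm > 0
        ys, xs, g_y, g_x, norm = ys[ok], xs[ok], g_y[ok], g_x[ok], norm[ok]
        uy, ux = g_y / norm, g_x / norm
        for i, r in enumerate(radii):
            for sign in (1.0, -1.0):
                cy = np.rint(ys + sign * r * uy).astype(int)
                cx = np.rint(xs + sign * r * ux).astype(int)
                inside = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
                np.add.at(votes[i], (cy[inside], cx[inside]), 1.0)
    acc = votes.sum(axis=0)
    if params.accumulator_sigma > 0:
        acc = ndi.gaussian_filter(acc, params.accumulator_sigma)
    if return_radius_votes:
        return acc, votes
    return acc


def select_centroids(accumulator: np.ndarray, params: DetectionParams,
                     radius_votes: np.ndarray | None = None,
                     frame: int = 0) -> list:
    """Pick accumulator maxima as detections.

    Local maxima with vote ≥ ``vote_fraction`` × global max are accepted
    greedily in descending vote order (ties in raster order), suppressing any
    candidate closer than ``maxima_min_separation`` to an already accepted
    one.  The radius estimate is the arg-max radius of the vote stack summed
    over a 3×3 neighbourhood of the centroid; without a vote stack the
    mid-range radius is reported.
    """
    acc = np.asarray(accumulator, dtype=float)
    vmax = acc.max()
    if vmax <= 0:
        return []
    is_max = acc == ndi.maximum_filter(acc, size=3, mode="constant")
    cand = is_max & (acc >= params.vote_fraction * vmax)
    ys, xs = np.nonzero(cand)
    order = np.lexsort((xs, ys, -acc[ys, xs]))  # vote desc, then raster order
    accepted: list = []
    min_sep2 = params.maxima_min_separation ** 2
    radii = params.radii
    for k in order:
        y, x = int(ys[k]), int(xs[k])
        if any((y - d.y) ** 2 + (x - d.x) ** 2 < min_sep2 for d in accepted):
            continue
        if radius_votes is not None:
            y0, y1 = max(0, y - 1), min(acc.shape[0], y + 2)
            x0, x1 = max(0, x - 1), min(acc.shape[1], x + 2)
            local = radius_votes[:, y0:y1, x0:x1].sum(axis=(1, 2))
            radius = float(radii[int(np.argmax(local))])
        else:
            radius = (params.radius_min + params.radius_max) / 2.0
        accepted.append(Detection(frame=frame, x=float(x), y=float(y),
                                  radius=radius, score=float(acc[y, x])))
    return accepted


def detect_cells(series, params: DetectionParams | None = None) -> list:
    """Run the full detection pipeline on every frame of a transmitted series.

    Per frame: resample by ``scale_factor``, compute the edge map and the
    gradient field, vote, select centroids, then map centroids and radii back
    to original-image coordinates.
    """
    if params is None:
        params = DetectionParams()
    s = params.scale_factor
    detections: list = []
    h, w = series.shape
    for f in range(series.n_frames):
        frame = np.asarray(series.frames[f], dtype=float)
        if s != 1.0:
            frame = rescale(frame, s, order=1, anti_aliasing=s < 1,
                            preserve_range=True)
        edges = compute_edge_map(frame, params)
        grad = gradient_field(frame, params.canny_sigma)
        acc, votes = circular_hough(edges, grad, params, return_radius_votes=True)
        for d in select_centroids(acc, params, radius_votes=votes, frame=f):
            x = min(max(d.x / s, 0.0), w - 1.0)
            y = min(max(d.y / s, 0.0), h - 1.0)
            detections.append(Detection(frame=f, x=x, y=y,
                                        radius=d.radius / s, score=d.score))
    return detections


def scaled_params_for_original(params: DetectionParams) -> DetectionParams:
    """Params re-expressed at original-image scale (for local re-detection)."""
    s = params.scale_factor
    if s == 1.0:
        return params
    return replace(
        params,
        radius_min=max(1, int(round(params.radius_min / s))),
        radius_max=max(2, int(round(params.radius_max / s))),
        maxima_min_separation=params.maxima_min_separation / s,
        scale_factor=1.0,
    )
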