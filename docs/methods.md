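# Methods

`motrack` analyses the motility of cells — designed around T lymphocytes —
in co-registered multi-channel 2D time-lapse microscopy: a transmitted-light
channel (bright-field, DIC or phase contrast) drives detection and tracking,
and reflection (IRM) plus up to two fluorescence channels are read out
locally along each track.  This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic test bed does and
does not show.

## Detection

Each transmitted-light frame is optionally resampled by `scale_factor` so
that cell radii land in the voting radius range, then:

1. **Canny edge map.** The frame is min-max normalised and edges extracted
   with Gaussian pre-smoothing `canny_sigma` (default 2 px).  The hysteresis
   thresholds `canny_low`/`canny_high` (defaults 0.1/0.25) are *fractions of
   the maximum gradient magnitude*, which makes the edge map — and hence
   detection counts — invariant under affine intensity changes.
2. **Gradient-directed circular Hough transform.** Every edge pixel casts
   one vote per radius in `[radius_min, radius_max]` (defaults 6–18 px) at
   the two positions offset along ± its gradient direction.  Voting along
   the gradient rather than over full circles costs O(edge px × radii) and
   concentrates votes at centres of circles whose boundary is only partially
   edged — the property that makes the detector usable on crowded,
   low-contrast cells.  Vote stacks are summed over radii and smoothed with
   `accumulator_sigma` (2 px) so imperfect circles produce one maximum.
3. **Centroid selection.** Local maxima with votes ≥ `vote_fraction` (0.35)
   of the global maximum are accepted greedily in descending vote order
   (raster order on ties, for determinism), suppressing candidates within
   `maxima_min_separation` of an accepted one.  The per-detection radius is
   the arg-max radius of the vote stack around the centroid.  Centroids are
   mapped back to original coordinates by 1/`scale_factor`; there is no
   sub-pixel refinement (tracking tolerates ≈ 2 px localisation error).

`maxima_min_separation` defaults to `radius_max` (18 px at reference scale).
A polarised (elliptical) cell spreads its votes into a ridge whose ends can
both become local maxima roughly 1.5 radii apart; a suppression radius at
the top of the radius range merges these duplicates while leaving genuinely
distinct cells (which sit at least a cell diameter apart) untouched.  With
the smaller values one might try first (e.g. `radius_min`), the detector
emits duplicate centroids on elongated cells and precision collapses.

## Tracking

Tracking is two-tiered; the design premise is that frame-to-frame
association should only be trusted where it is unambiguous, and everything
else should be decided globally.

**Tier 1 — confident segments.** A segment end at frame t−1 is extended by a
detection at frame t only when that detection is its *single* candidate
within the link radius `r` and no other segment end has that detection in
range.  Every other configuration (zero candidates, two candidates, a
contested detection) terminates the segments involved; contested or
unclaimed detections open fresh one-point segments.  Segments are therefore
frame-contiguous stretches over which identity is certain.

`r` defaults to 25 px.  At the reference acquisition (0.439 μm pixels,
33.3 s between frames) a 10 μm/min cell moves a *median* of ≈ 12.6 px per
frame, so a link radius near that value breaks half of its steps; 25 px
clears the per-step displacement distribution's upper tail while staying
well under the ≈ 40 px mean cell spacing at ~50 cells per 512 px field.

**Tier 2 — global joining.** Every feasible predecessor/successor pair
(successor starts 1–`max_gap` frames after the predecessor ends, default 4,
and the end-to-start distance is within `v_max × gap`) gets a similarity

    s = w_time·s_time + w_space·s_space + w_speed·s_speed,      weights (0.25, 0.5, 0.25)
    s_time  = 1 − (gap−1)/max_gap
    s_space = 1 − d/(v_max·gap)
    s_speed = 1 − |v̄_a − v̄_b| / max(v̄_a, v̄_b)

clamped to [0, 1].  When either segment is a single point (no speed
evidence) the sum is renormalised over the time and space terms instead of
inventing a neutral speed score.  A rectangular Hungarian assignment with a
per-row "no-join" column priced at `join_threshold` (0.4) picks the globally
optimal set of joins; accepted joins are chained transitively into tracks.
Joined tracks keep their frame gaps — positions are never interpolated, and
all downstream speeds divide by the actual elapsed time.

`v_max`, when not set explicitly, is estimated as 2 × the 95th percentile of
*consecutive-frame nearest-neighbour* displacements pooled over all
detections.  Within-segment steps are the wrong basis: they are
right-censored at `r` (the steps that exceeded `r` are precisely the ones
that broke segments), and a bound fitted to them rejects the most important
joins.  The nearest-neighbour statistic is independent of `r`, and the 2×
headroom keeps tail steps joinable.  On synthetic movies this choice is what
makes tracking accuracy flat (variation < 0.1 in thresholded ATA) across a
threefold sweep of `r`.

Tracks shorter than `min_track_len` (5 frames) are discarded.  Manual edit
lists (CSV of split/join operations) are applied splits-first, then joins,
mirroring how curation lists are compiled from visual inspection.

## Feature extraction

The tracked centroid is the anchor for *local* segmentation in every
channel: a square box of half-size 2.5 × `radius_max`/`scale_factor` is
cropped around it (clipped at borders, offsets recorded).  Local — rather
than global — thresholding is the point of the design: IRM backgrounds drift
in space and time, so no global threshold exists, while inside a ~70 px box
Otsu's threshold is reliable.

* **Reflection (IRM):** foreground is the class *below* the Otsu threshold
  (close cell–glass contact appears dark).  A watershed on the negated
  distance transform, seeded at distance maxima, separates touching
  footprints; the region whose centroid is nearest the box centre (within
  `max_center_distance`, default `radius_max`) is kept.  Contact area is
  pixel count × pixel_size²; areas below `min_area_um2` (3 μm², real
  contacts are at least a few μm²) are reported as zero and not attached.
  A track counts as attached if *any* of its positions is attached.
* **Fluorescence:** same procedure with foreground above the threshold;
  the feature is the mean raster intensity under the mask.  Otsu tends to
  place the threshold high on noisy fluorescence, biasing the mask toward
  bright pixels and hence the mean slightly upward; this known bias is left
  uncorrected (it is a property of the method, and small on the synthetic
  test bed).
* **Validity guard:** a box containing no object at all (e.g. the reflection
  crop of an unattached cell) must yield *no* segmentation, but Otsu happily
  splits pure background noise in two.  The segmentation is accepted only if
  the two classes separate by at least 4 pooled within-class standard
  deviations — background-only splits reach ≈ 2.7, genuine footprints ≈ 8+.
  Without this guard the attachment readout would be meaningless.
* **Transmitted light:** Canny edges are extracted inside the box and the
  circular-Hough accumulator computed; connected supra-threshold vote
  regions seed a marker-based watershed whose elevation surface is the
  smoothed edge map, with the box border as the background seed.  The flood
  from a cell seed meets the background flood at the cell's edge ring, so
  the seeded basin is the cell interior.  (Connected vote *regions* — not
  individual peaks — are used as seeds because an elongated cell's vote
  ridge contains several peaks that must not split the cell.)  The largest
  region whose centroid is within the gate is the cell; its second-moment
  ellipse gives the aspect ratio (major/minor axis), the morphological
  polarity readout.  Moment ellipses were chosen over Feret boxes as the
  standard, rotation-invariant definition.

**Cell typing from vital dyes.** Per track, the per-observation ratios
(fluor1+ε)/(fluor2+ε) (ε = 10⁻³; a missing channel contributes 0) are
pooled by their *median* — a single frame in which the dim channel fails to
segment makes the ratio explode, so the mean is fragile — and compared to
`ratio_high` (2.0) and `ratio_low` (0.5).  Tracks in between stay
unassigned.

## Motility metrics

Instantaneous speed (μm/min) divides the Euclidean step by the actual
elapsed time, so joins' frame gaps do not bias it.  Turn angle is the
unsigned angle between successive displacement vectors (absent when a step
is zero: a stationary cell has no direction).  The arrest coefficient is the
fraction of instantaneous speeds strictly below 0.5 μm/min.  The confinement
index is net displacement over path length in [0, 1] (1 = straight motion);
of the definitions in circulation this bounded "confinement ratio" was
chosen for being testable and standard.  Per-track summaries (mean speed,
median turn angle, arrest coefficient, confinement index, path length, net
displacement, mean contact area, attachment, cell type) feed population
tables, including group medians optionally normalised to a named control
group.  Hypothesis testing is deliberately out of scope — the summary tables
are the interface to external statistics tools.

## Performance evaluation

Ground truth is a set of per-frame bounding boxes grouped into tracks
(ViPER-dialect XML).  Detector output is converted to boxes as the square of
side 2 × radius centred on the detection.

* **FDA / SFDA:** per frame, boxes are matched one-to-one by Hungarian
  assignment on Jaccard similarity; FDA = Σ matched Jaccard / mean box
  count; SFDA averages FDA over frames where either side has a box.
* **STDA pair score / ATA:** a ground-truth/result track pair scores the
  mean per-frame Jaccard over the *union* of their frames (frames where one
  side is absent contribute 0 but stay in the denominator).  The Hungarian
  algorithm maximises the total score one-to-one; ATA = Σ pair scores /
  mean track count.  The *thresholded* variant counts per-frame Jaccard
  ≥ 0.4 as 1 so that small localisation offsets are not punished; both
  variants are always reported.
* **Feature evaluation:** per frame, result cells are matched to
  ground-truth cells by centroid distance (Hungarian with a gate, default
  `radius_max`); matched pairs yield absolute and relative errors per
  feature, summarised by the median absolute relative error.  A matched
  pair whose result lacks a feature the truth has counts as relative error
  1.0 — extraction failures are not silently dropped.

## Synthetic movies

The generator exists so that every stage is testable without external data.
Defaults emulate a chemokinesis benchmark acquisition: 0.439 μm pixels,
33.3 s frame interval, 512 px (≈ 225 μm) square field, and two equal
vital-dye-labelled populations with mean speeds 5 and 10 μm/min (log-normal
per-step speeds, SD 1.5/2.0 μm/min), 50% of cells attached with irregular
dark IRM footprints of mean area 25 μm², dye intensities (0.8, 0.1) /
(0.1, 0.8) against a 0.05 fluorescence background, and Gaussian noise
SD 0.03 on every channel.

Motion is a persistent random walk with reflective boundaries and soft
pairwise repulsion below 26 px (cells never overlap at default density).
The heading increment SD is `exp(coupling·(s−μ)/μ)/√turn_concentration`
with coupling −1, so fast steps turn less — reproducing the inverse
speed–turn relationship of amoeboid motility, where cells alternate between
straight runs and slow turning phases.

Rendering: transmitted cells are soft-edged ellipses (+0.12 over a 0.5
background) whose aspect ratio performs a bounded random walk up to
`aspect_max` (1.9) — enough edge contrast for the detector without DIC
shading physics; the reflection background drifts slowly in space and time
(amplitude 0.04), which is precisely the property that defeats global
thresholding; fluorescence cells are uniform disks at their population's
dye intensity.  Ground truth (boxes, outlines, per-frame features, realised
footprint pixel areas) is exported in formats the I/O and evaluation
modules read back.

**What the synthetic bed does not show.** Real DIC/IRM optics, halos,
photobleaching, cell division, out-of-focus drift, shape changes during
contact, and intensity heterogeneity within a cell are all absent.  Passing
tests demonstrate the algorithms' correctness and their behaviour under the
stated noise and motion models — not performance on any particular
microscope's data, for which parameters (radius range, scale, thresholds)
must be tuned with the preview tool.

## Problem sizes used in the test suite

Accuracy checks run on movies of 10–110 cells, 15–100 frames and fields of
256–900 px — small enough to run on one CPU in minutes, large enough for
stable statistics (e.g. ≥ 100 tracks for population-parameter recovery, 100
frames for detection precision/recall).  The headline feature-accuracy
benchmark uses 30 cells × 50 frames at default rendering noise.

## Known limitations

* The contested-termination rule makes tier-1 fragmentation grow with `r`;
  accuracy is then carried by the joining stage, which tolerates this well
  (see the `v_max` discussion) but cannot fully undo identity swaps during
  prolonged close encounters.
* Aspect-ratio accuracy is moderate: the watershed interior of the edge
  ring underestimates elongation for weakly contrasted tips.
* Otsu's upward bias on mean fluorescence (above) is inherent to the
  segmentation choice.
* The trackers and metrics are 2D; 3D stacks are out of scope, as are
  proprietary microscope formats and channel registration.
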