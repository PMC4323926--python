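# motrack

Integrative analysis of cell motility from multi-channel 2D time-lapse
microscopy.  `motrack` detects and tracks motile cells — it was designed
around fast amoeboid T lymphocytes — in the transmitted-light channel, then
uses each tracked centroid to segment the *same cell* locally in
co-registered secondary channels: interference reflection microscopy (IRM)
for substrate contact area and attachment, up to two vital-dye fluorescence
channels for cell-type identity and intensity, and the transmitted channel
itself for morphological polarity.  Per-track motility statistics and
population summary tables come out the other end, together with a
performance-evaluation suite (SFDA/ATA against bounding-box ground truth)
and a synthetic movie generator that makes the whole pipeline testable with
no external data.

## Method at a glance

* **Detection** — Canny edge extraction followed by a gradient-directed
  circular Hough transform: each edge pixel votes at offsets ±r along its
  gradient direction for r ∈ [r_min, r_max]; smoothed accumulator maxima are
  cell centroids.  Works on partial, non-contiguous boundaries, so crowded
  low-contrast cells are still found.
* **Tracking** — two tiers.  Nearest-neighbour links are accepted only when
  unambiguous (a single mutual candidate within radius *r*), yielding
  confident track *segments*; segments are then joined end-to-end by a
  Hungarian assignment over a compatibility similarity
  `s = 0.25·s_time + 0.5·s_space + 0.25·s_speed`, accepting joins with
  `s > 0.4`.  Tracks shorter than 5 frames are discarded.
* **Feature extraction** — a square box around each track position is
  segmented locally (Otsu + watershed for reflection/fluorescence; edge +
  Hough-seeded watershed for transmitted light), immune to the
  spatiotemporal background drift that defeats global thresholds in IRM.
* **Motility metrics** — instantaneous speed (μm/min, gap-aware), turn
  angle, arrest coefficient (fraction of speeds < 0.5 μm/min), confinement
  index (net displacement / path length), per-track and population tables.
* **Evaluation (SFDA/ATA)** — Jaccard-based detection accuracy per frame
  (SFDA) and one-to-one track correspondence accuracy (ATA, raw and with
  per-frame Jaccard ≥ 0.4 counted as 1), plus per-frame centroid-matched
  feature-error tables.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Generate a synthetic two-population movie, run the pipeline, and score the
result against the exported ground truth:

```bash
echo '{"n_cells": 8, "n_frames": 10, "field_size_px": 256}' > demo/params.json
motrack synth -o demo/movie --seed 33 --params demo/params.json
cat > demo/config.json <<'EOF'
{
  "calibration": {
    "pixel_size_um": 0.439, "frame_interval_s": 33.3,
    "channels": {
      "transmitted": "demo/movie/transmitted.tif",
      "reflection":  "demo/movie/reflection.tif",
      "fluor1":      "demo/movie/fluor1.tif",
      "fluor2":      "demo/movie/fluor2.tif"
    }
  },
  "output_dir": "demo/out"
}
EOF
motrack run -c demo/config.json
motrack score --ground-truth demo/movie/ground_truth.xml \
    --tracks demo/out/tracks.csv -o demo/report.json
```

The run prints

```
8 cells × 10 frames written to demo/movie
8 tracks, 80 observations written to demo/out
```

and the scorer prints (numbers from this seed)

```json
{
  "sfda": 0.7280588206144198,
  "ata": 0.7280588206144197,
  "ata_thresholded": 1.0,
  "jaccard_threshold": 0.4,
  "n_pairs": 8
}
```

meaning: all 8 ground-truth cells were recovered as single, complete tracks
(8 pairs, thresholded ATA = 1.0 — every per-frame overlap clears the 0.4
Jaccard bar), while the raw scores of ≈ 0.73 reflect the few-pixel box
mismatch between detected squares and the annotated ellipse bounds, which
the thresholded variant is designed to forgive.  `demo/out/summary.csv`
holds the
per-track motility table — mean speed, arrest coefficient, confinement
index, attachment flag and dye-based cell type — ready for downstream
statistics.

Other CLI verbs: `motrack preview` (edge map / accumulator / overlay images
for one frame, for parameter tuning), `motrack batch` (many experiments,
combined summary), `motrack edit` (apply a split/join correction list).
The same functionality is available as a library (`import motrack`).

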