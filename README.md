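# nvuquant

Neurovascular-unit histomorphometry and statistics toolkit:

* **Vessel-area segmentation** — an 8-bit, macro-faithful filter stack
  (min-max normalize → Gaussian blur 2 px → Sobel edge magnitude → local
  variance 5 px → local median 3 px → subtract the image SD → multiply 255
  → invert) followed by 8-connected particle analysis with a size filter,
  yielding per-image vessel percent area.
* **Morphometry** — percent area above a fixed experiment-wide threshold,
  skeleton-based curvilinear length (orthogonal step = 1 px, diagonal =
  √2 px), and length-based pericyte coverage of the vessel centerline.
* **Cell detection** — multi-scale Laplacian-of-Gaussian blob detection
  with greedy non-maximum suppression, plus one-to-one greedy matching of
  double-positive cells across two channels.
* **Group statistics** — per-animal aggregation (the animal is the unit of
  inference), relative-to-control normalization with SEM, pooled-variance
  unpaired t (Welch optional), one-way ANOVA + Tukey HSD, Pearson R², and
  a ΔΔCt/fold-change pipeline with a 2-SD differential-expression rule.
* **Synthetic micrographs** — a seeded generator of multi-channel scenes
  (curvilinear vessel tubes, pericyte bands and somata, soma-like cells
  with double-positive pairing, punctate deposits, background gradient,
  Poisson + Gaussian noise) with exact pre-noise ground truth, and cohort
  generation with planted multiplicative group effects.

Because the 8-bit stages round and clamp after every step, the filter
primitives are checked exactly against naive brute-force references in the
test suite; segmentation and detection are validated against the
simulator's ground truth (segmentation R² ≈ 0.98 across 30 scenes with
true vessel fractions 2–15 %).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (filter oracle
equivalence, segmentation validation, planted-effect recovery, t-test null
calibration, counting accuracy, the ΔΔCt worked example, statistics-oracle
agreement, and full-pipeline determinism).

## CLI

```sh
nvuquant simulate --seed 0 --out scenes/                 # one scene + truth
nvuquant simulate --cohort --seed 0 --out cohort/        # groups x animals x images
nvuquant segment --channel COL4 --min-area 25 --out seg.csv IMG.tif ...
nvuquant area --channel GFAP --threshold 60 --out area.csv IMG.tif ...
nvuquant count --channel IBA1 --out counts.csv IMG.tif ...
nvuquant coloc --a C1QA --b IBA1 --radius 5 --out coloc.csv IMG.tif ...
nvuquant coverage --vessel-channel COL4 --pericyte-channel PDGFRB --out cov.csv IMG.tif ...
nvuquant ddct ct.csv --normalizer Actb --control-group young --out fc.csv
nvuquant stats measurements.csv --control-group young --out stats.csv
nvuquant run --config cfg.yaml --manifest cohort/manifest.csv --image-root cohort/
```

`run` executes the full batch (quantify → per-animal aggregation → group
tests chosen by group count) and writes `per_image.csv`, `per_animal.csv`,
`group_stats.csv`, `summary.json` and a config echo for provenance.

## Notes and caveats

* The subtraction constant "σ" is interpreted as the sample standard
  deviation of the current (post-median) image, recomputed per image and
  recorded in `params_used` for audit; a fixed numeric value can be
  configured instead.
* The variance stage dilates vessel edges by roughly the blur + variance
  radii, so absolute area fractions overshoot truth while remaining
  strongly linear in it; comparisons across groups and validation fits are
  unaffected.
* Min-max normalization stretches structureless (no-signal) fields to full
  range, which saturates the edge/variance stages; such fields are outside
  the algorithm's domain.
* Skeleton lengths carry ±2 px thinning end effects; lengths of rotated
  masks agree within the same tolerance.
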