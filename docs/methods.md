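# Methods

## Scope and data model

`retscreen` models a paired-eye DR screening study.  Each patient
contributes a left and a right eye; DR status is a patient-level label
shared by both eyes, while measurements (fundus photograph, tear sample)
are per eye.  An analysis record (`EyeRecord`) carries the per-eye MA
count, the 34-protein tear concentration vector and the DR label; a
record enters a given screening model only when the features that model
consumes are present.  Results are computed and reported at eye level.

## Microaneurysm detector

The detector assumes MAs appear in the green plane as approximately
circular intensity dips, smaller than retinal vessels' width-wise extent
but of comparable darkness, over a background whose illumination varies
slowly relative to a 35 px window.

Chain and defaults (`DetectorConfig`):

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `shade_window_px` | 35 | px | median window large enough to be flat over lesions, small enough to track illumination |
| `clahe_clip` | 0.05 | fraction | strong enough that lesion peaks reach comparable height across tiles; see "Calibration" |
| `clahe_tiles` | 8×8 | tiles | standard tiling; 32 px tiles at 256² |
| `smooth_window_px` | 3 | px | speckle suppression before reconstruction |
| `opening_disk_px` | 10 | px | disk diameter (10×10 bounding box); structures that cannot contain it are "small" |
| `residual_threshold` | 0.1 | fraction of max | binarisation of top-hat minus opening; see "Calibration" |
| `min_area_px` / `max_area_px` | 1 / 120 | px | single-pixel candidates are legitimate for ~3 px lesions; 120 caps vessel fragments |
| `match_tolerance_px` | 3 | px | standard lesion-scoring tolerance |
| `candidate_score_threshold` | 0.5 | probability | symmetric operating point |
| GBM | 200 rounds, depth 2, lr 0.1 | — | shallow boosted trees on 5 features |

Two polarity/semantics choices are forced by operator algebra rather than
stated anywhere: (i) top-hat by reconstruction extracts *bright* peaks,
so the shade-corrected residual (in which lesions are negative) is
sign-inverted and min–max rescaled before CLAHE; (ii) the opening by the
disk *removes* sub-disk structures, so candidates are read off the
difference between the top-hat image and its opening, not off the opening
itself.  The alternative reading (candidates from the opening) would by
construction keep only structures at least as large as the disk,
contradicting the goal of detecting small circular objects.

"Mean intensity in the morphologically opened image" is computed over the
opened top-hat grid; since the opening removes sub-disk structure, this
feature is near zero for true lesions and positive for fragments of
larger structures, which is exactly what makes it discriminative.

Candidate ground-truth matching is greedy nearest-first, one-to-one,
within 3 px.  Candidate ordering is deterministic (sorted by centroid),
and all windowed filters use reflective boundaries.  Coordinates are
0-based (row, col).

### Calibration

Two defaults were calibrated against the package's own recoverability
requirement (≥95% of planted noiseless 3–7 px lesions recovered within
3 px) rather than taken from common practice:

* `clahe_clip = 0.05`: at the conventional 0.01 the equalisation is
  nearly the identity on these images, and lesion peak heights stay
  proportional to their local contrast, so a threshold relative to the
  image maximum (set by vessel junctions) drops the smallest lesions.
* `residual_threshold = 0.1`, `min_area_px = 1`: the 3×3 median filter
  roughly halves the peak of a 3 px Gaussian dip, and in noiseless
  images the supra-threshold core of such a lesion is often a single
  pixel.

With these defaults, extraction recall over held-out synthetic fixtures
is ≈0.97–0.98 and end-to-end recall/precision (after the candidate
classifier, trained on 60 fixtures) ≈0.96/0.96.

## Tear-fluid QC

Secretion rate = collected volume / collection time, in µL/min, exact
quotient.  The 5–15 µL/min acceptance window is read as a closed
interval.  Any missing protein concentration excludes the eye (no
imputation); the rate criterion is assessed first so every exclusion has
one cause, which makes the QC report's accounting identity
(`n_input = n_retained + n_rate_excluded + n_incomplete_excluded`) hold
trivially.  Concentrations are opaque positive abundances; no transform,
scaling or normalisation is applied before modelling — the tree
ensembles are scale-invariant and the naive Bayes model never sees them.

## Screening models

* `image_nb` — naive Bayes on the single MA-count feature.  Default
  class-conditional is Gaussian with empirical class priors; a Poisson
  conditional (the natural count family, with +0.5/+1 smoothing) is
  available via `nb_variant="poisson"`.  With one feature, "naive Bayes"
  reduces to a one-dimensional Bayes classifier; the Gaussian default is
  the conventional choice and the variant exists because a Gaussian on
  small counts is a knowingly rough approximation.
* `proteomics_gbm` — gradient boosting (200 rounds, depth 2, lr 0.1,
  seeded) on the 34 concentrations.
* `combined_gbm` — the same boosting on proteins with the MA count
  appended as the 35th feature.

Probabilities are thresholded at `decision_threshold` (default 0.5,
configurable — published sensitivity/specificity pairs imply some
operating point that is never printed).

## Evaluation

Stratified k-fold (default k = 10) repeated (default 10×).  Fold
assignment deals each class round-robin with a continuing pointer, so
fold sizes differ by at most one while both classes spread evenly.  For
each validation fold, any non-validation record whose fellow eye is in
the fold is excluded from that fold's training set only — it is never
dropped from validation elsewhere.  This removes the optimistic bias of
training on the highly correlated fellow eye of a validated record.

Metrics per fold: sens, spc, acc, prec, npv, F1 = 2·prec·sens/(prec+sens),
LRP = sens/(1−spc), LRN = (1−sens)/spc.  A zero denominator yields NaN;
aggregation (mean, sample SD over all k×repeats fold values) skips NaNs
and reports `n_defined` per metric.  Aggregating at fold level (rather
than per repeat) is a deliberate choice; the SDs therefore describe
fold-to-fold spread at validation sizes of n/k eyes and are large for
small cohorts.  Folds whose training set degenerates to a single class
are skipped and counted.  Display rounding is half-away-from-zero to two
decimals; computation keeps full precision.

## Synthetic generators

The generators emulate the *structure* that the pipeline consumes, not
retinal photorealism:

* **Fundus images** (default 256×256): green channel = base level 0.55
  + low-order polynomial illumination surface (peak-to-peak 0.15) −
  vessels − lesions + optional Gaussian noise, clipped to [0,1]; red and
  blue channels are affine in green.  Vessels are cubic splines through
  random waypoints, rasterised with a 2–5 px round brush at fractional
  contrast 0.3 — enough to create the false-positive surface the
  candidate classifier must learn to reject.  MAs are 2-D Gaussian dips
  of depth `ma_contrast` (default 0.2) whose quoted diameter is the full
  width at 20% depth; placements avoid vessels and each other (≤1 px
  overlap), and a placement that cannot be satisfied raises an error
  naming the constraint.  Diameters are capped below the 10 px opening
  disk by construction.
* **Proteomes**: log-normal concentrations around fixed per-protein
  baselines (log-SD 0.5); in DR patients the first
  `n_informative_proteins` (default 10) log-coordinates shift upward by
  `protein_effect_size` standard deviations.
* **Cohorts** (default 52 patients): patient-level DR status
  (default fraction 0.75, matching 39/52), per-eye Poisson MA counts
  (defaults 6.0 DR / 0.8 non-DR — clearly separated, as in a cohort
  where image screening alone performs well), secretion rates centred on
  10 µL/min, and independent per-eye Bernoulli exclusion flags for the
  two loss causes (defaults 0.09 / 0.20).  The enrolment-arithmetic
  reproduction (104 → 74 eyes) assigns exact exclusion counts
  deterministically instead of sampling.

Everything is a pure function of spec + seed.

What the generators do **not** emulate — hence what green tests do not
show about clinical data: optic disc and fovea, haemorrhages and
exudates, image-quality variation, camera noise characteristics, real
protein covariance and batch effects, and any dependence between a
patient's two eyes beyond the shared label.  Detector performance on
these images bounds behaviour on real photographs only qualitatively.

## Pipeline

`run_pipeline` executes simulate → detect → proteomics-QC → train →
evaluate from one config dictionary.  Stage seeds derive from the global
seed as `crc32("<seed>:<stage>") mod 2³¹`, so a rerun with the same
config reproduces byte-identical artifacts; the manifest records a
SHA-256 hash per artifact, per-stage status and elapsed time, and the
aggregate metrics of the three models.  The detect stage trains the
candidate classifier on the first half of the simulated images' ground
truth and scores all images; screening models consume the cohort table.

## Problem sizes

The test suite and `scripts/acceptance.py` use 256×256 images, 50
evaluation fixtures (≈250 lesions) with a 60-fixture training set for
detector scoring, 200-eye cohorts for null/permutation checks, and ten to
twenty 300-eye cohorts with 5-fold CV for the fusion property — sizes at
which the measured quantities are stable to a few percent while a full
run stays comfortably on one CPU.

## Known limitations

* The candidate feature set is fixed at the five listed features; small
  compact vessel fragments genuinely overlap lesions in this space, which
  bounds end-to-end precision/recall around 0.96–0.98 on synthetic data.
* The relative binarisation threshold is keyed to the image maximum and
  therefore sensitive to the single brightest structure; a robust
  quantile reference would be less brittle but changes the stated
  semantics.
* `image_nb`'s Gaussian conditional on counts is a deliberate
  convention; use the Poisson variant for principled count likelihoods.
* Aggregate SDs conflate fold-to-fold and repeat-to-repeat variation;
  per-repeat aggregation is not implemented.
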