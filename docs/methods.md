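# Methods

## Scope and model

`neuromorph` implements a whole-slide morphometry pipeline for EvG-stained
peripheral-nerve cross-sections: supervised per-pixel tissue classification
with a random forest, shape-based refinement of nervous tissue into
organized fascicles vs neuroma tissue, per-sample composition measures
including the normalized deviation index, and small-cohort statistics
relating composition to pain scores. Because its intended inputs are
clinical slides that cannot ship with the code, the package also contains a
first-class synthetic-data generator that defines the study conditions all
tests run under.

## Synthetic cohort generator

The generator emulates a 12-patient cohort: 4 control nerves and 3
non-painful neuromas (NRS 0), and 5 painful neuromas with NRS
`[5, 6, 7, 8, 8]` — the minimal integer multiset with median 7 and range
5–8 for n = 5, chosen deterministically. Sexes follow the cohort pattern
(controls 2M/2F, non-painful 3M, painful 4M/1F); ages are drawn uniformly
from each group's range and carry no information about pain.

Each sample is a square RGB image (default 512 px, 0.5 µm/px — a typical
200× whole-slide scale) containing an elliptical nerve profile filled with
connective tissue into which components are packed:

* **organized fascicles** — ellipses with axis ratio ≥ 0.78; every placed
  component is verified to have circularity ≥ 0.7;
* **unorganized (neuroma) tissue** — jagged star polygons that may overlap
  one another and merge into clusters; after every placement the *merged*
  connected component is verified to have circularity ≤ 0.5, so the truth
  masks are separable by any threshold in (0.5, 0.7);
* **adipose vacuoles** and **erythrocyte specks** — circles, packed without
  margins (they are never shape-analyzed);
* 2-px margins around nervous components keep truth components distinct
  even under slight prediction fuzz.

Placement is distance-transform-guided dart throwing: candidate centers are
pixels whose free-space EDT exceeds the candidate's bounding radius, with
geometric size shrinking as the canvas saturates. Per-class pixel budgets
give nervous tissue 40 % of the nerve area by default (adipose 15 % in
controls, 10 %/8 % in non-painful/painful neuromas — the direction of the
group contrast the statistics stage should detect; erythrocytes 1.5 %). The
organized share of nervous tissue targets 0.95 in controls, 0.60 in
non-painful neuromas, and ramps linearly from 0.30 (NRS 5) to 0.10 (NRS 8)
in painful ones; achieved fractions are guaranteed within ±0.1 of target
(in practice within ~0.01) or the render fails loudly. A `null_cohort_spec`
variant sets a flat 0.5 target for every group, decoupling composition from
NRS for type-I-error calibration.

Coloring uses an invented EvG-like palette (connective pink-red, nervous
tissue tan/brown, adipose near-white, erythrocytes saturated red,
background off-white) — only class separability matters, since no color
calibration exists for real slides. On top of the per-class base color the
generator adds per-component color jitter (σ = 3), a ±4 % low-frequency
illumination gradient, smooth shared texture (Gaussian-filtered noise,
σ = 2 px, amplitude 5), and i.i.d. Gaussian pixel noise (σ = 8 on a 0–255
scale). This defeats a bare color-lookup rule while remaining learnable —
the point of the synthetic task is to exercise the pipeline's mechanics
against exact ground truth, not to match the difficulty of real histology.
What passing tests show is that the implementation is correct and recovers
encoded effects; they do not show that the feature set suffices for real
EvG variability (stain batch effects, blur, folds, debris are not
modeled).

## Pixel classification

Features are an ilastik-style bank per RGB channel: raw color plus
Gaussian smoothing, Gaussian gradient magnitude and local variance
(E[x²]−E[x]² under a Gaussian window) at scales {1, 2, 4, 8} px with
reflective boundaries — 39 channels. The classifier is a scikit-learn
`RandomForestClassifier` (100 trees, unlimited depth, fixed seed,
single-threaded for determinism). Class imbalance is handled by a
per-class pixel cap (50 000 by default; the end-to-end pipeline uses 3 000,
which keeps the training matrix at 18 000 rows — fit in seconds at held-out
accuracy far above the 0.9 recovery band). Subsampling is keyed to sorted
(image-hash, row, col) pixel coordinates, so training is invariant to the
order in which images are supplied. A 10 % stratified hold-out reports
pixel accuracy; classes with a single labeled pixel stay in the training
split. Prediction is tiled (1024² tiles) with an overlap equal to the
filter support radius (4σmax, 32 px at default scales), which makes tiled
and untiled outputs bit-identical away from image borders — verified by
test.

## Fascicle shape filter

"Roundness" is the circularity shape factor C = 4πA/P², clamped to [0, 1],
with the perimeter measured as the length of the marching-squares boundary
at level 0.5 after a circular moving-average smoothing (window 5 vertices).
This estimator was chosen over lattice-edge counting and Crofton formulas
because it is simultaneously accurate for digitized disks (C ≈ 0.99 at
r = 100), squares (C ≈ 0.80 vs the analytic π/4) and thin bars (C ≈ 0.03),
where edge counting under-rates disks and Crofton over-rates squares by
more than the downstream threshold margins. A single-pixel component is
defined to have C = 1.

Components are formed over the union of organized + unorganized pixels
(8-connectivity by default) and re-labeled wholesale — the fascicle, not
the pixel, is the unit being filtered. The threshold is 0.6, centered
between the generator's constructed classes (≥ 0.7 vs ≤ 0.5) and
configurable. Components below `min_component_px = 50` are re-assigned to
connective tissue: sub-fascicle specks are classifier noise, not
mini-fascicles (set 0 to disable). Total non-background pixel count is
conserved by construction.

## Composition and deviation index

Absolute area per class is `pixels × mpp² / 10⁶` (mm²); relative area
divides by all non-background pixels. Erythrocytes are included in the
denominator by default ("percent of total tissue area"); a config flag
excludes them. The normalized deviation index
`(unorganized − organized)/max(unorganized, organized)` is scale-invariant
and antisymmetric; at `unorganized = organized = 0` the formula is 0/0 and
the index is reported as undefined (`None`) and excluded from correlations
rather than silently coded as 0.

## Statistics

Normality is screened with a Lilliefors-style one-sample KS test
(statsmodels, parameters estimated from the sample, table-based p), "normal"
meaning p > 0.05. Group comparisons use Student's equal-variance t when
both groups pass the screen (Welch available by flag), otherwise a
two-sided Mann–Whitney U with mid-rank tie handling — exact by full
enumeration of all C(n, n_a) assignments when the pooled size is ≤ 12
(at most 924 combinations), normal approximation beyond. Degenerate groups
(zero variance, or too small for the normality screen, n < 4) are routed to
Mann–Whitney automatically — the natural handling for variables like
"unorganized tissue in controls" that cannot be normal. Spearman
correlations use mid-ranks with the two-sided t approximation on n − 2 df;
a seeded Monte-Carlo permutation p (default 10⁴ draws) is available as an
option. Under the cohort's tied NRS pattern the t approximation's type-I
error is ≈ 5–6 % at n = 8, verified by the null-calibration test. Raw
p-values are reported (no multiplicity correction by default, matching the
small-cohort reporting convention); a Benjamini–Hochberg column is emitted
on request. Figures annotate p < 0.05 with `*` and p < 0.01 with `**`;
violins show a white median dot and an IQR bar; quantiles use linear
interpolation.

The full report covers: control vs pooled neuromas and painful vs
non-painful, each for relative and absolute areas of the four solid tissue
classes; Spearman vs NRS among neuroma samples for relative unorganized,
relative organized and the deviation index (undefined indices dropped);
and exploratory age-vs-NRS and NRS-by-sex tests.

## Problem sizes and numerical choices

The end-to-end checks run one 12-sample cohort at 512² (training capped at
3 000 px/class); the type-I calibration renders 200 cohorts of the 8
neuroma samples at 256² with a lighter tissue load (nervous 30 %, adipose
5 %) — controls do not enter the correlation, so rendering them would add
cost without information. Determinism: every stochastic step derives from
an explicit seed through `numpy.random.SeedSequence`; probability channels
sum to 1 within 1e-6 (random-forest vote averaging); argmax ties harden to
the lower class index.

## Known limitations

* The palette, noise model and component geometry are invented; accuracy
  numbers on synthetic data say nothing quantitative about real slides.
* "Roundness" definitions, the 0.6 threshold, and forest hyperparameters
  are package choices (configurable), not values calibrated on clinical
  material.
* The segmentation does not distinguish intrafascicular from
  extrafascicular connective tissue, and no stain normalization or
  whole-slide-format (SVS/NDPI) reading is provided.
* Group sizes of 3–5 give the comparisons little power; the package
  reports raw p-values and directions, not clinical claims.
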