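# Methods

`hsibrain` implements a patch-based tissue-classification pipeline for
intraoperative visible/near-infrared (VNIR) hyperspectral images of the
exposed human brain, aimed at delineating glioblastoma margins. The pipeline
is: reflectance calibration → band-group averaging → supervised ant-colony
band selection → non-overlapping spectral-spatial patching → a 3D–2D hybrid
convolutional network (with 2D CNN, pixel-wise DNN and linear-SVM baselines)
→ leave-one-patient-out cross-validation (LOPOCV). A synthetic cohort
generator with the statistical structure of a small clinical VNIR brain
database makes every stage testable without clinical data.

## Data model

A cube is a `(rows, cols, bands)` float array with a strictly increasing
wavelength axis in nm; interleave variants (BIL/BSQ/BIP) exist only in the
ENVI files on disk. Annotations use five codes: 0 unlabeled, 1 normal tissue
(NT), 2 tumor tissue (TT), 3 blood vessels (BV), 4 background (BG); ground
truth is sparse because only pixels annotated with high certainty carry a
label. The modelled sensor has 826 bands on 400–1000 nm. Its grid is
piecewise linear through (band 1, 400 nm), (band 55, 440 nm), (band 699,
902 nm), (band 826, 1000 nm): mid-range sampling is slightly denser than at
the extremes, and the closed trim window [440, 902] nm keeps exactly 645
bands. A uniform grid would keep 636, so the anchored grid is what makes the
trim count come out right.

## Preprocessing

Reflectance calibration is `R = (I_raw − I_dark) / (I_white − I_dark)`
against a white-tile and a closed-shutter capture; references may be a
single spectrum broadcast over pixels or a full cube, and the denominator
must be strictly positive wherever applied. Trimming drops the noisy sensor
extremes (default window above). Band averaging replaces consecutive
non-overlapping groups of eight bands by their mean — applied to the full
uncut 826-band spectrum (826 → 103), because selected wavelengths may fall
below the trim cutoff and 103 is the only count compatible with later
selecting 100 bands; a trailing incomplete group (2 bands) is discarded so
all groups have equal weight. Trimming remains an independent path used
before pixel-wise baselines.

## Ant-colony band selection

Vertices of a complete graph are candidate bands; a route of `n_select`
distinct vertices is a candidate subset. The next vertex is drawn with
probability ∝ τ_ij^α · η_j^β among unvisited vertices (the first ∝ row sum
of τ, same exponents). After each generation the generation-best route
deposits `Q · F(f_best)` on **every pair of its vertices** — the deposit
condition is membership of both endpoints in the best route, so the whole
clique of the subset is reinforced; depositing only on consecutively
traversed pairs would reinforce 4 of the ~5,000 edges for a 5-subset and
exploitation would never build up. All edges evaporate by `τ ← ρ·τ` and are
floored at `τ_min`.

Fitness is the held-out accuracy of a one-vs-rest linear SVM on the
restricted features, averaged over three fixed stratified 70/30 splits.
Averaging matters: a single split's accuracy on a few hundred validation
pixels has a standard error of several points, and the arg-max over hundreds
of noisy evaluations systematically returns lucky subsets (winner's curse);
three splits cut that noise by √3 at modest cost. The fitness pixels are
subsampled **class-balanced** (equal counts per class): under the cohort's
natural imbalance (~10 % tumor) plain subset accuracy barely penalizes a
subset that ignores tumor entirely, and the search discards exactly the
tumor-discriminative wavelengths it exists to find.

Defaults follow the reference configuration: 30 ants, 30 generations,
α = 1.0, β = 10.0, ρ = 0.5, Q = 10 (we read the lower-case `q` of the source
configuration as the deposit constant Q, and "strategy 2" as
generation-best-deposits), F = identity, τ₀ = 1. Two defaults differ from
the obvious choices and are deliberate:

* **η is uniform by default** (a per-band Fisher-ratio heuristic is
  available via `heuristic="fisher"`). With a supervised fitness the
  pheromone trail already encodes learned desirability; a static heuristic
  raised to β = 10 dominates sampling so completely (odds ratios ~10⁵
  between spectral regions) that bands the heuristic under-rates — in our
  cohorts the 600–800 nm tumor window, whose within-class variance is
  inflated by illumination and inter-patient gain — are never drawn at all,
  even when the window-only subset has fitness 1.0.
* **τ_min = 0.05** rather than a vanishing floor. With ρ = 0.5 every
  non-reinforced edge decays to any tiny floor within ~15 generations, after
  which route construction is frozen on the first noisy winner; a moderate
  floor keeps a constant exploration pressure.

Selected subsets are reported as sorted indices with wavelengths, plus
contiguous-range merging (adjacent-on-grid bands join into closed nm
intervals) for compact reporting.

## Patching and normalization

Images are tiled into non-overlapping P × P tiles anchored at the top-left
corner (default P = 11; remainder rows/columns are dropped, not padded).
A tile's label is the modal class among its *labeled* pixels; unlabeled
pixels do not vote, and tiles with no labeled pixel are discarded. Equal
modal counts break by the tumor-sensitive priority TT > BV > NT > BG — a
missed tumor patch is the clinically costly error. Patches are standardized
per band with statistics computed on training folds only.

## Classifiers

All five classifiers share one `fit` / `predict_proba` contract with class
probability columns in (NT, TT, BV, BG) order, so the evaluation stage is
classifier-agnostic.

* **Hybrid 3D–2D CNN** — four valid (unpadded) 3-D convolutions over
  (row, col, band), a reshape folding the spectral axis into channels, two
  2-D convolutions, then three dense layers ending in a 4-way softmax.
  The 2-D stage uses same padding: after four valid 3 × 3 spatial
  reductions an 11-pixel patch is down to 3 × 3, which cannot absorb two
  more valid 3 × 3 convolutions. Default kernels: 8@(3,3,7), 16@(3,3,5),
  32@(3,3,3), 32@(3,3,3); 64@(3,3) twice; dense 256, 128, 4; ReLU; dropout
  0.4 on dense layers. A reduced preset (`HybridArchSpec.small`: 4/8/8/8
  and 16/16 filters, dense 64/32/4, kernels clamped to the available
  extent) is used for the single-CPU experiments.
* **2D CNN baseline** — three same-padded 2-D convolutions with the
  spectral axis as input channels, one 2 × 2 average pooling, three dense
  layers. It can only mix bands linearly in its first layer, which is the
  point of the comparison.
* **1D DNN baseline** — pixel-wise dense network with hidden widths 28 and
  40, ReLU, softmax; patches feed it their center pixel.
* **Linear SVM** — one-vs-rest on flattened patch intensities; probability
  scores are the softmax of decision margins (classes absent from training
  get probability zero).
* **Hybrid + SVM** — the trained hybrid as a feature extractor (flattened
  activations of its last convolutional layer) feeding the linear SVM.

The networks run on a purpose-built numpy layer engine (im2col convolutions,
Adam, softmax cross-entropy, single precision). All initialization and
shuffling randomness derives from explicit seeds; repeated runs are
bit-identical on a fixed BLAS. Training defaults: Adam, lr 1e-3, batch 64,
epochs configurable (50 general default; 20 in the standard synthetic
experiment). Inverse-frequency class weighting is implemented but off by
default. Gradients of every layer type are verified against central finite
differences, and the convolutions against `scipy.signal.correlate`, in the
test suite.

## Evaluation

Per class, one-vs-all reduction gives accuracy (TP+TN)/total, sensitivity
TP/(TP+FN) and specificity TN/(TN+FP); the overall multiclass accuracy is
trace/total of the 4 × 4 confusion matrix (per-class one-vs-all accuracies
are also reported for comparability). A metric whose denominator has no
support in the truth — e.g. tumor sensitivity for a patient without labeled
tumor — is n/a (`None`), never zero, and n/a folds are excluded from
cross-fold means and standard deviations (folds are otherwise weighted
equally). Per-class AUC is one-vs-all over all thresholds with half credit
for ties (computed via scikit-learn, cross-checked against an O(n²)
concordance oracle).

LOPOCV builds one fold per patient; all images of the held-out patient form
the test set, and band selection, normalization statistics and training use
training-fold data only (fold disjointness is asserted on every run). A
config flag can reuse one global band subset instead, mirroring a single
up-front selection run; the leakage-safe per-fold mode is the default.
Classification maps paint every full tile with its predicted class color
(green/red/blue/black for NT/TT/BV/BG, white margins), at patch granularity
— the patch is the classification unit, and pixels inherit their tile's
label.

## Synthetic cohorts

The generator emulates the *statistical shape* of the clinical database, not
its radiometry: 826 bands on the anchored grid; four classes with prevalence
proportional to the database's labeled-pixel totals (NT 0.305, TT 0.107,
BV 0.238, BG 0.350); 12 images over 9 patients with the database's
multiplicity pattern (three patients contribute two images); sparse labels
(default 15 % of pixels); per-patient smooth multiplicative spectral
perturbations shared across a patient's images (scale 0.05); a smooth 2-D
illumination gain field (amplitude 0.1); additive Gaussian pixel noise
(sd 0.01). Class mean spectra are Gaussian bumps on linear baselines: NT is
a smooth tissue-like curve rising into the NIR; TT equals NT plus a fixed
difference supported in 600–800 nm scaled by a separability knob in [0, 1]
(0 makes tumor spectrally identical to normal tissue — the hard failure
case); BV has hemoglobin-like double dips near 540/575 nm; BG is flat and
dark. Spatial layout is the argmax over per-class smoothed Gaussian random
fields with biases iterated to hit the prevalence targets — compact blobby
regions for every class whose borders genuinely mix classes inside tiles.
Raw counts are synthesized by inverting the calibration against generated
white/dark references, so the calibration stage is exercised for real. A
`degrade_illumination` transform attenuates reflectance smoothly above a
cutoff wavelength, reproducing the out-of-distribution acquisition whose
infrared illumination was filtered.

What passing tests on this cohort do **not** show: robustness to specular
highlights, blood pooling, resection-induced spectral change, registration
error, or real inter-patient biological variability. The signatures are
stylized; the generator's purpose is discriminative structure at known
wavelengths with realistic imbalance, sparsity and patient grouping.

A separate fixture, `make_informative_window_pixels`, produces labeled pixel
spectra in which only a 10-band window discriminates the four classes and
each window band carries an independent random class-mean pattern
(amplitude 1.0 against unit noise, 150 pixels per class). Non-redundant
window bands are essential to the fixture's purpose: if window bands were
redundant, two of five selected bands would saturate the SVM fitness and
full-window recovery would not be implied by optimality. An exhaustive
search over band pairs on a 12-band instance confirms in the tests that the
optimum lies inside the window.

## Standard experiment sizes

The standard synthetic experiment (used by the acceptance checks and
`scripts/acceptance.py`) runs the default 12-image / 9-patient cohort at
64 × 64 pixels: calibrate → average (826 → 103 bands) → per-fold ACO
selection of 24 bands with 6 ants × 5 generations on a balanced 600-pixel
subsample → 11 × 11 patches (~300 per cohort) → reduced-preset hybrid (or
2D CNN) trained 20 epochs → 9-fold LOPOCV. These sizes were chosen once as
a desk-scale single-CPU experiment; the reference search configuration
(30 ants × 30 generations, 100 bands from 103) is exercised separately for
its structural properties. On this experiment the hybrid reaches a mean
overall accuracy around 0.9 with tumor sensitivity around 0.8, and at
separability 0 tumor sensitivity collapses toward 0 while tumor specificity
stays near 1 — the qualitative failure signature of a patient whose tumor
spectra match normal tissue.

## Numerical and degenerate-input conventions

Nearest-wavelength lookups break ties to the lower band index. Zero-variance
bands are floored at 1e-8 during standardization (with a warning).
Equal-fitness subsets resolve to the earliest found. Probability rows sum to
1 within 1e-6 (float32 softmax). The ENVI writer emits float64 rasters and
full-precision wavelength lists, so round trips are bit-exact. BG-majority
tiles are kept as a training class (background is a class of the problem,
not clutter). Stage transitions on cubes are forward-only
(raw → reflectance → trimmed → averaged → selected) to prevent accidental
re-calibration.

## Known limitations

Patch-level evaluation under-counts boundary errors relative to dense
pixel-level truth. The 2-D baseline sees pre-selected bands, which narrows
the gap to the hybrid on spectrally easy cohorts. The engine is CPU-bound
and single-threaded; the default (non-reduced) hybrid on 100-band patches
is practical for inference and small trainings but slow for large cohorts.
The synthetic generator's class geometry is isotropic blobs; real vessels
are curvilinear.
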