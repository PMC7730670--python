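# hsibrain

Patch-based tissue classification for intraoperative hyperspectral imaging
of the exposed human brain, aimed at glioblastoma margin delineation.
Each pixel of a visible/near-infrared (VNIR, 400–1000 nm) hyperspectral
cube carries a near-continuous reflectance spectrum — a tissue fingerprint —
and the package classifies 11 × 11-pixel spectral-spatial patches into
normal tissue (NT), tumor tissue (TT), blood vessels (BV) and background
(BG).

The pipeline:

1. **Reflectance calibration** against white-tile and closed-shutter
   references: `R = (I_raw − I_dark) / (I_white − I_dark)`.
2. **Dimensionality reduction**: noisy-extreme trimming (keep 440–902 nm;
   645 of 826 bands on the modelled sensor) and/or averaging of consecutive
   groups of eight bands (826 → 103).
3. **Ant-colony band selection**: ants build candidate band subsets on a
   pheromone graph; the next band is drawn ∝ τ_ij^α·η_j^β, the
   generation-best subset deposits ρ·τ + Q·F(f_best) on all pairs of its
   bands, and the objective is the held-out accuracy of a linear SVM on the
   restricted spectra.
4. **Patching**: non-overlapping 11 × 11 tiles labeled by the majority
   class of their labeled pixels.
5. **Classification**: a 3D–2D hybrid CNN (four valid 3-D convolutions over
   space × wavelength, a reshape folding spectra into channels, two 2-D
   convolutions, three dense layers, 4-way softmax), with 2D CNN, pixel-wise
   1D DNN, linear SVM and hybrid-features→SVM baselines behind one
   train/predict contract.
6. **Evaluation**: leave-one-patient-out cross-validation (every image of
   the held-out patient is test data; band selection and normalization are
   fit on training folds only), per-class sensitivity/specificity/AUC with
   explicit n/a handling, overall accuracy, and classification-map
   rendering.

Because the in vivo clinical database cannot ship with the code, the
package includes a synthetic cohort generator reproducing its statistical
shape — 826 bands, 12 images over 9 patients, sparse imbalanced labels,
per-patient spectral variability, and a separability knob that can make
tumor spectra identical to normal tissue (the clinically hard case). See
`docs/methods.md` for the full model description.

## Worked example

Run the standard synthetic experiment (12 images / 9 patients at 64 × 64
pixels, per-fold selection of 24 bands, reduced hybrid preset, 20 epochs):

```python
from hsibrain import TT
from hsibrain.pipeline import run_synthetic_lopocv

summary = run_synthetic_lopocv(seed=1, model="hybrid")
acc, std = summary.mean_std("overall_accuracy")
tt_sens, _ = summary.mean_std("sensitivity", TT)
print(f"folds={len(summary.reports)} accuracy={acc:.3f}+-{std:.3f} "
      f"TT sensitivity={tt_sens:.2f}")
```

prints

```
folds=9 accuracy=0.887+-0.044 TT sensitivity=0.78
```

Nine folds, one per patient: mean overall patch accuracy 0.887, and 78 % of
tumor patches in held-out patients are recognized as tumor. Re-running with
`separability=0.0` (tumor spectrally identical to normal tissue) collapses
tumor sensitivity toward 0 while tumor specificity stays near 1 — the
classifier stops finding tumor but does not over-call it.

The same experiment is available from the shell:

```sh
hsibrain run --seed 1 --model hybrid --out results/run1
```

which writes a per-fold `summary.csv`, and a `manifest.json` with all
parameters and derived per-stage seeds. Individual stages are exposed as
`hsibrain synth | calibrate | select-bands | make-patches | train | predict
| crossval`.

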