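# choroidseg

Automated choroid segmentation and subfoveal choroidal thickness (SfChT)
measurement for OCT B-scans, plus the longitudinal statistics used to study
choroidal responses to myopia-control spectacle lenses.

The choroid — the vascular layer between the retinal pigment epithelium (RPE)
and the sclera — thickens within days when the eye is exposed to myopic
defocus, and choroidal thickening is studied as an early biomarker of
myopia-control efficacy. Quantifying it requires segmenting the choroid on
enhanced-depth-imaging OCT B-scans, locating the fovea, and reading the
thickness under it, repeatedly, across thousands of scans of a two-year
trial. `choroidseg` implements that whole measurement pipeline and the
downstream cohort analysis:

- **Phantoms** (`choroidseg.phantom`): synthetic layered B-scans (vitreous /
  retina with foveal pit / RPE / speckled choroid with lacunae / sclera) with
  pixel-perfect ground-truth choroid masks, so every stage is testable
  without clinical data.
- **Networks** (`choroidseg.nn`): a U-Net with batch normalization and a
  ResNet-style residual encoder–decoder, both with the bottleneck replaced by
  a **strip-pooling block** (whole-row and whole-column pooled strips, 1-D
  mixing, sigmoid gate) that grows the receptive field along the thin,
  image-wide choroid band; late fusion averages the two probability maps.
  Implemented on a small numpy reverse-mode autodiff engine that is
  gradient-checked against numeric differentiation.
- **Training / evaluation** (`choroidseg.train_eval`): Adam + dice loss,
  online augmentation (±10° rotations, horizontal flips,
  brightness/contrast jitter), and evaluation by Dice similarity
  coefficient, DSC(X, Y) = 2|X∩Y| / (|X|+|Y|), and average symmetric surface
  distance (ASSD) between mask boundaries.
- **Post-processing** (`choroidseg.postprocess`): threshold at 0.5, keep the
  maximally connected component, Otsu-based fovea localization in the central
  25 A-scans (thinnest-retina column), per-column thickness in µm, and the
  six-scan (3 horizontal + 3 vertical) SfChT average.
- **Cohort statistics** (`choroidseg.cohort`): a seeded simulator of a
  two-arm trial (defocus-incorporated-multiple-segments "DIMS" lenses vs
  single-vision "SV" controls, visits from 1 week to 24 months), and the
  analyses: change from baseline, baseline-covariate-adjusted group means
  ± SEM, percent change, Pearson associations, and hierarchical multiple
  regression (ΔR², standardized betas) of 12-month axial elongation on
  early choroidal change after controlling age and gender.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

prints (one CPU, ~1 minute):

```
dice loss: 0.505 (epoch 1) -> 0.201 (epoch 20)
held-out DSC 0.9959 +/- 0.0012 (max 0.9971)
held-out ASSD 0.047 +/- 0.013 px
fusion of identical models reproduces the single model exactly: True
```

i.e. after 20 epochs on 30 tiny phantoms the post-processed segmentation
overlaps the ground truth at DSC ≈ 0.996 and the predicted choroid boundary
sits within a twentieth of a pixel of the true one on held-out phantoms.
`examples/04_cohort_statistics.py` runs the longitudinal analysis on a
simulated cohort (78 DIMS vs 80 SV subjects):

```
 1w: DIMS   7.24 ± 1.52 um   SV  -3.37 ± 1.50 um   (p = 3.18e-06)
12m: DIMS  14.07 ± 1.36 um   SV -10.24 ± 1.34 um   (p = 6.42e-25)
relative one-week thickening in the DIMS arm: 2.5% of baseline
24-month correlation of choroid change vs axial elongation: r = -0.370 (thicker choroid, slower eye growth)
hierarchical regression: R2 0.106 -> 0.161 (delta 0.055); beta(3-month choroid change) = -0.238
```

The treated arm's choroid thickens within a week and keeps thickening
through the first year while the control arm thins; subjects whose choroid
thickens more elongate less; and 3-month choroidal change predicts 12-month
elongation beyond age and gender.

There is also a CLI (`choroidseg simulate|train|segment|evaluate|measure|
cohort-simulate|cohort-stats|demo`); `choroidseg demo --seed 0` runs the
whole chain end-to-end into one output directory.

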