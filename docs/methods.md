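# Methods

This note documents the models, conventions and numerical choices behind
`choroidseg`, in the order data flows through the package.

## Synthetic B-scan phantoms

A phantom is rendered column by column from integer boundary rows: vitreous
down to the inner limiting membrane row, a retinal band whose per-column
thickness dips at the foveal pit, a 2-pixel hyper-reflective RPE line at the
bottom of the retina, the choroid band, and sclera below. Band
reflectivities (vitreous 0.02, retina 0.65, RPE 0.95, choroid 0.30, sclera
0.15, lacunae 0.10) are cartoons chosen so that (a) an Otsu threshold
separates the bright retina+RPE class from everything else and (b) the
choroid is visibly distinct from both RPE and sclera. The ground-truth mask
is drawn from the same integer rows as the image, so per-column mask
thickness equals the generating profile exactly; only the intensity image
receives multiplicative Gaussian speckle (clipped to [0, 1]) and seeded dark
elliptical lacunae confined to the choroid band. This is deliberately not a
physical speckle or light-propagation model — it exists to give every
downstream stage exact, seeded ground truth.

Two presets: `full` is 496×768 with a 3.87 µm/pixel axial pitch
(Spectralis-like; the pitch is a convention — acquisitions vary and the
value is always overridable), and `tiny` is 64×96 for CPU-scale training
and tests. One deliberate distortion in `tiny`: the foveal pit is sharp
(Gaussian sigma 2.5 columns) rather than realistically flat, because at
64-pixel image height a smooth pit rounds into a multi-column tie at the
tip and "the thinnest retina column" stops being well defined. A visit is
emulated as three horizontal plus three vertical line scans whose choroid
profiles get a small seeded integer jitter (default ±2 px).

What passing on phantoms does **not** show: robustness to real OCT speckle
statistics, shadowing, motion artifacts, ambiguous chorio-scleral
boundaries, or anatomical variation. The pipeline's logic and arithmetic
are validated; its clinical accuracy is not.

## Segmentation networks

Both networks map a single-channel image to a same-size probability map
through a final logistic unit (single output channel; the binary task
needs no softmax). The U-Net uses double 3×3 conv + batch-norm + ReLU
blocks, 2×2 max pooling, nearest-neighbour upsampling and skip
concatenation. The "ResNet-101" branch is realized as a residual encoder
(basic blocks, stride-2 stage entries; stage plan [3, 4, 23, 3] at the
`paper` preset, one block per stage at `tiny`) with a lightweight
upsampling decoder and additive skips — a classifier backbone alone cannot
emit dense masks, so an encoder–decoder reading is the only sensible one.

The bottleneck of both is the strip-pooling block: features are average-
pooled into an H×1 column strip and a 1×W row strip, each mixed by a 1-D
convolution, broadcast back, summed, passed through a sigmoid, and used as
a gate multiplying the identity path. The 1-D convolutions use replicate
padding so a constant feature map yields a constant gate — with zero
padding the strip borders would break that invariant. Late fusion is the
elementwise mean of two probability maps (probabilities, not pre-squash
scores, are averaged — an interpretive choice).

Everything runs on an in-package numpy reverse-mode autodiff engine
(convolution via im2col, max-pool, nearest upsampling, batch-norm with
running statistics, elementwise ops). Every operator's backward pass is
verified against central-difference numeric gradients in the test suite.
Weights are He-normal, seeded; inference is fully deterministic given the
initialization seed.

`tiny` (base 8 channels, depth 2, ~40k parameters) is the default; `paper`
(base 64, depth 4, ~42M parameters for the U-Net) is constructible but far
beyond desk-scale CPU training and is only built, never trained, in tests.

## Training and evaluation

Adam (defaults: lr 3e-3, betas 0.9/0.999) minimizes the dice loss
1 − (2Σpy + s)/(Σp + Σy + s) with smoothing constant s = 1. Online
augmentation applies one seeded rotation within ±10° and an optional
horizontal flip identically to image and mask (mask resampled
nearest-neighbour, so it stays strictly binary; exposed borders filled
with the image's background intensity and mask 0), then
brightness/contrast jitter to the image only. Saturation jitter is a
documented no-op on single-channel data. Training is reproducible given
the config seed: shuffling, augmentation draws and initialization all
derive from it.

Evaluation post-processes predictions (0.5 threshold, largest component,
hole fill) before computing metrics, then reports per-image and aggregate
DSC and ASSD. Conventions fixed for testability:

- DSC of two empty masks is 1.0 (perfect agreement).
- Surface points are foreground pixels with at least one background
  4-neighbour, the image border counting as background; distances are
  Euclidean between pixel centres.
- ASSD uses the pooled symmetric form (Σᵢdᵢ + Σⱼdⱼ*)/(N_seg + N_gt). The
  per-index "paired" form (1/N)Σ(dᵢ + dᵢ*) is only defined when both
  surfaces have the same number of points and is available behind a flag.
- The training problem sizes used throughout (30 training phantoms, 10
  held-out, 20 epochs, tiny preset) are the package's desk-scale defaults;
  they reach DSC ≈ 0.99 on held-out phantoms in under a minute per seed.

## Post-processing and SfChT

Probability maps are binarized at 0.5 (inclusive: p = 0.5 is foreground).
The maximally connected foreground component (8-connectivity by default)
removes false positives; ties between equal-size components go to the one
containing the lexicographically smallest (row, col) pixel. Interior holes
(lacunae) are filled before thickness is counted, since they belong to the
choroid band.

Fovea localization reads "the central 25 pixels" as the central 25 A-scan
columns (an even-width image centres the band one column to the left). The
band is thresholded by Otsu followed by one isodata refinement — the
midpoint of the two class means — because on a strongly bimodal histogram
the raw Otsu argmax sits at the low edge of the between-class plateau,
within a few noise standard deviations of the choroid intensities. Retina
pixels are counted per column (optionally restricted to rows above the
choroid's top boundary when a mask is available); the column with the
fewest retina pixels is the fovea, ties broken toward the image centre and
then leftward.

Thickness is foreground-pixel count per column × axial pitch (µm/pixel) —
equivalent to boundary subtraction for a simply connected, hole-filled
column and robust to lacunae. Values are kept at full precision internally
and rounded to 2 decimals only at CSV serialization, so recovering a
phantom's configured SfChT through the whole chain is bit-exact. A visit's
SfChT is the mean over its (up to six) line scans; a scan with no choroid
at its subfoveal column is excluded with a logged warning.

## Cohort simulation and statistics

The simulator emulates the trial arms it is parameterized for: 78 treated
(DIMS) and 80 control (SV) subjects, baseline SfChT N(280.95, 54.30²) vs
N(259.53, 49.36²) µm, ages ~10 ± 1.5 years. Follow-up SfChT is baseline +
per-visit group mean change + a per-subject "responder" effect
(SD 8 µm, shared across that subject's visits — individual choroidal
responsiveness is consistent) + independent per-visit noise (SD 10 µm).
The visit-change profiles use the printed trial values where available
(1 week +6.75/−3.17 µm, 1 month +8.58 µm DIMS, 12 months +13.64/−9.46 µm)
and monotone interpolations consistent with the described trajectory
elsewhere (DIMS rising then plateauing, SV thinning steadily).

Axial elongation at 12 months is generated from a linear model on age,
gender and 3-month choroidal change (coefficients −0.025 mm/yr,
−0.010 mm, −0.0020 mm/µm, noise SD 0.12 mm), and 24-month elongation
extends it with a −0.0030 mm/µm coupling to 24-month choroidal change;
SER change follows elongation at −1.8 D/mm. These couplings are negative
by construction: choroidal thickening accompanies slower eye growth. With
these defaults the simulated standardized betas (age ≈ −0.29, 3-month
choroid ≈ −0.2) and the 24-month ΔSfChT–ΔAL correlation (≈ −0.37) sit in
the range reported for such cohorts.

Analyses:

- **Change from baseline** per subject and variable; subjects lacking a
  baseline are excluded with a warning.
- **Adjusted group change** fits change ~ group + centred baseline by OLS
  and reports each group's prediction at the grand-mean baseline with its
  standard error (statsmodels). If baselines have zero variance the
  covariate is dropped and adjusted means equal raw means. A mixed
  between-within ANOVA is deliberately not reimplemented; the per-visit
  covariate-adjusted contrast answers the same group-difference question.
- **Percent change** = 100 × change / baseline, rounded to 1 decimal for
  display.
- **Hierarchical regression**: all variables (gender coded male = 1) are
  z-scored; Model 1 regresses the outcome on age + gender, Model 2 adds
  one choroid-change block; reported are R² per model, ΔR², standardized
  betas and two-sided coefficient p-values. R² is non-decreasing across
  the nested models by construction of least squares, and the suite
  verifies it on every simulated replicate.

## Known limitations

- Phantoms are geometric cartoons; no claim of clinical-grade accuracy
  transfers from them.
- The `paper`-scale networks are buildable but not trainable at desk
  scale; no pretrained weights ship with the package.
- The cohort simulator is homoscedastic Gaussian with no dropouts,
  no diurnal effects and no measurement-device drift.
- Only 2-D line scans are modelled — no volume scans, no regional
  (ETDRS-grid) thickness maps, no sub-pixel boundary interpolation.
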