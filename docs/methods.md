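# Methods

## Problem and model

The package targets a binary classification problem from 2D breast DWI: given
a single axial slice pair (b = 0 and b = 800 s/mm²) with pixel spacing
340/256 ≈ 1.328 mm, plus four categorical clinical markers, predict whether
an IHC-equivocal (2+) HER-2 tumor is FISH-amplified. Three logistic
*rad-scores* (linear predictors over selected radiomic features) are built
from the intratumoral region, the 4-mm peritumoral ring, and their combined
candidate pool; the combined score and any independently predictive clinical
markers then enter a multivariate logistic model rendered as a nomogram.

The ADC map follows the two-point mono-exponential model
`ADC = (ln SI₀ − ln SI)/(b − b₀)` (mm²/s). Non-positive intensities are
floored at the smallest positive value in the image before the logarithm;
the count of floored pixels is logged. This preserves ranking and avoids
infinities; flooring only ever affects noise-dominated background pixels.

## Segmentation

The intratumoral ROI is the classic five-step recipe on the b800 image:
Otsu threshold (256-bin histogram over the seed region's observed range,
ties resolved to the lowest qualifying threshold) → binary mask → erosion
with a 4×4 square element → largest 8-connected component → dilation with
the same element. Conventions that the recipe leaves open are pinned and
regression-tested:

- the even 4×4 element anchors at the **top-left pixel of its central 2×2
  block** (`origin=-1` in scipy terms);
- the peritumoral ring uses a Euclidean-distance-transform threshold at
  `round(4 mm / spacing)` pixels (3 px at the default spacing, nearest
  rounding with ties-to-even) rather than iterated square dilations, to
  approximate an isotropic 4-mm distance; the step-5 dilation of the tumor
  itself keeps the square element as specified;
- masks are row-major boolean arrays, 0-based indices.

On small lesions the 4×4 opening erodes boundary detail, so segmentations of
wobbly-contoured phantoms reach Dice ≈ 0.8 against ground truth while clean
disks of radius ≥ 15 px exceed 0.9; both are properties of the recipe, not
of the implementation.

## Feature bank (2,504 features)

14 shape descriptors of the intratumoral mask, and per channel (b0, b800,
ADC) × region (intra, peri): 5 first-order statistics, 45 GLCM, 125 Laws and
240 Gabor features — 14 + 6 × 415 = 2,504. Pooling always uses the five
statistics mean/median/SD/skewness/kurtosis with population (n) denominators;
skewness is m₃/m₂^1.5 and kurtosis m₄/m₂² (Pearson, not excess), both defined
as 0 for zero variance.

Choices the feature list itself does not fix:

- **Normalization.** Per ROI per channel, intensities are clipped to the
  ROI's μ ± 3σ band and affinely mapped to [0, 255]. The affine map is
  applied to the whole cropped neighborhood so convolutions have valid
  support, but statistics and pooling use in-mask pixels only. Laws and
  Gabor operate on these continuous values; the GLCM on the 8-bit quantized
  levels (half-open equal-width bins, right edge inclusive at 255).
  Whether intra and peri should share one normalization is unstated
  upstream; per-ROI treatment is the default here.
- **GLCM ensemble.** The 45 = 9 descriptors × 5 statistics structure needs
  an ensemble to pool over; the package uses 4 directions (0°, 45°, 90°,
  135°) × 5 distances (1–5 px) = 20 symmetric, normalized, in-mask-pair
  co-occurrence matrices. Entropies use log₂ with 0·log 0 ≡ 0; correlation
  and the information measures are 0 when degenerate.
- **Laws kernels.** Exactly as printed in the source feature table,
  including W5 = (−1 2 0 −2 −1) whose element sum is −2 (the textbook wave
  kernel ends with +1); consequently only filters containing an E5/S5/R5
  factor annihilate constants. Responses are pooled as absolute values.
- **Gabor bank.** Frequencies (0, 2, 4, 8, 16, 32) cycles per image width
  (the 256-px reference grid) at orientations (0°, 22.5°, 45°, 67.5°, 90°,
  112.5°, 135°, 167.5°) — the non-uniform 167.5° entry is kept verbatim,
  with a config switch for the uniform 157.5° grid. Isotropic Gaussian
  envelope with the one-octave bandwidth rule σ = (1/πf)·√(ln2/2)·3;
  f = 0 degenerates to a unit-mass Gaussian smoother borrowing the σ of the
  lowest nonzero frequency. Kernels truncate at 3σ capped at a 32-px radius
  (the f ≤ 2 envelopes would otherwise span the grid); responses are pooled
  as magnitudes.
- **Convolution boundary.** Reflect padding; extraction crops to the ROI
  bounding box plus a margin at least as wide as the largest kernel radius
  (plus the largest GLCM offset), so every pooled response pixel sees only
  real image data and features are exactly translation invariant.

z-scoring fits per-column mean/SD (population) on the training cohort only
and applies them everywhere; zero-variance columns pass through as 0 with a
flag.

## Reproducibility filter

Two readers' feature tables are compared per feature with the two-way
random-effects, absolute-agreement, single-measurement ICC(2,1), computed
vectorized from the ANOVA mean squares (the consistency form ICC(3,1) is
selectable). Features with ICC strictly above 0.8 are retained. The second
reader is emulated by a boundary perturbation of the segmentation: a smooth
random field modulates the signed-distance threshold by up to the requested
magnitude in pixels, clamped with a warning when it would swallow the mask.

## Feature selection

1. **Wilcoxon screen** — two-sided rank-sum per feature, mid-rank ties,
   normal approximation with continuity correction (exact enumeration of
   label assignments for total n ≤ 12); keep p < 0.1 strictly.
2. **MRMR** — greedy MID criterion: relevance = mutual information of the
   equal-frequency 8-bin discretized feature with the label; redundancy =
   mean MI with the already-selected set; 20 picks (MIQ and other bin counts
   are config options).
3. **Backward stepwise** — from the full logistic model, repeatedly remove
   the feature whose removal most decreases AIC; stop when no removal
   decreases it; ties break lexicographically. This ΔAIC < 0 rule is the
   standard likelihood-ratio-with-AIC-penalty stopping rule. Note its exact
   null behavior: a pure-noise feature survives when its deviance
   contribution exceeds 2, which happens with probability ≈ 0.157 per
   feature — so null final sets are *small* (mean ≈ 1.6 of 10 candidates)
   but not usually empty.

The intratumoral pool includes the shape features (they describe the
intratumoral mask); the combined pool is the concatenation of the intra and
peri pools ahead of the screen.

## Logistic fitting and separation

Primary fits use maximum likelihood (IRLS). Non-convergence, exploding
coefficients or non-finite standard errors are treated as (quasi-)complete
separation, where the MLE does not exist. The fallback is **Firth's
Jeffreys-prior penalized logistic regression** rather than a token ridge
penalty: with a near-zero ridge the separated fit's deviance collapses to
zero and AIC-guided elimination then always prefers a separating overfit
subset (observed concretely as training AUC 1.0 with chance-level held-out
AUC at desk-scale n). Firth's penalty 0.5·log|I(β)| keeps coefficients,
standard errors and the penalized-likelihood AIC finite and honest, and is
the standard remedy for separation in small cohorts. Separated fits are
flagged on the model object.

Rad-scores are linear predictors including the intercept (config flag
`include_intercept`). Odds ratios use Wald CIs on the log scale; the
nomogram screen keeps univariate p < 0.05 candidates, refits them jointly,
and retains multivariate p < 0.05 survivors as independent predictors. The
points scale assigns each predictor β(x − x_ref) rescaled so the largest
observed contribution range spans exactly 0–100 points, with x_ref the end
of the observed range minimizing the contribution.

## Evaluation

AUC is the Mann–Whitney pair statistic; variance, CIs and paired model
comparisons use DeLong's placement-value components with normal
approximation (CIs truncated to [0, 1], zero-variance flagged). Operating
points maximize Youden's J over midpoints between adjacent unique scores
(plus sentinels; ties → lowest cutoff); sensitivity/specificity/accuracy
CIs are percentile bootstrap over 2,000 class-stratified case resamples with
the cutoff re-estimated per resample. Calibration is decile-grouped observed
vs. predicted with a lowess smooth; decision curves use net benefit
`TP/n − (FP/n)·p_t/(1−p_t)` over a 0.01–0.99 grid (default). The cohort
chi-square is Pearson without continuity correction; group comparisons of
rad-scores use Welch's t-test.

## Phantom generator

Each case is a single mass-like lesion — an ellipse (axis ratio 0.6–1.0)
with a smooth low-harmonic radial perturbation (≤ 10% amplitude) — with area
drawn log-normally around a 352 mm² median, truncated to [195, 1512] mm², on
a 256×256 grid at 1.328 mm spacing. The tissue model is two-compartment:
background b0 ≈ 600 (5% smooth spatial variation) with ADC 1.8×10⁻³ mm²/s,
lesion ADC 1.0×10⁻³ mm²/s, and the lesion's b800 mean set to background
b800 + 150 (the configurable contrast), making the lesion b800-hyperintense
with reduced ADC. Gaussian noise (σ = 10) is added per channel and clipped
at zero (Rician approximation; exact Rician sampling is a flag).

The class signal lives in texture *composition*, not amplitude: lesion (and,
at half amplitude, a 6-mm peritumoral band of) multiplicative texture is a
mixture √(1−w)·low + √w·high of a unit-variance smooth field and a
unit-variance band-pass (difference-of-Gaussians) field, with the
high-frequency energy fraction w = 0.3 + 0.2·texture_effect for positive
cases and 0.3 for negatives. Holding total texture variance fixed is
essential: per-ROI μ ± 3σ normalization removes any amplitude effect, so the
signal must sit in spectral shape, which the Laws/Gabor/GLCM families read
out. With texture_effect = 0 the renderer's draws are label-independent
(byte-identical images for the same stream). Clinical covariates are drawn
independently given the label from the study's class-conditional marginal
rates (e.g. ER-positive 58/97 vs 112/126); covariate–covariate dependence is
not modeled because only marginals are reported. The cohort split shuffles
case indices deterministically and takes the first round(n·train_fraction)
as training.

What the phantoms do *not* emulate: breast anatomy, partial-volume boundary
blur, coil inhomogeneity, reader variation in seed placement, or any
dependence of lesion size/shape on class. Passing tests therefore show that
the pipeline recovers a planted, normalization-robust spectral texture
difference at realistic noise — not that real HER-2 2+ tumors carry such a
difference.

## Problem sizes in the test suite

End-to-end experiments run on cohorts of 112 phantoms (84/28 split at the
study's positive fraction) with the texture-carrying families (shape,
first-order, Laws), 10 seeds per texture-effect level {0, 0.5, 1.0} — sizes
chosen so the stepwise stage operates near the n/k regime it is designed
for while a full grid remains desk-scale. Statistical calibration checks use
500 replicates (DeLong type-I error and CI coverage) and n = 5000 (logistic
recovery). The single-case feature-bank check extracts the full 2,504-feature
bank.

## Known limitations

- The exact GLCM ensemble, Gabor bandwidth/truncation and signed-vs-absolute
  pooling of the original study are unknowable from the feature table alone;
  the defaults above are pinned, config-exposed choices, not reconstructions.
- 2D only; single slice; no wavelet/LoG channels; no IBSI naming claims.
- The AIC stepwise rule retains occasional noise features by construction
  (see above); at n/k well below ~8 the Firth fallback engages often and
  in-sample AUCs are optimistic — held-out cohorts are the meaningful
  readout, as in the tests.
- Appendix-level coefficient values of the original models are not printed
  in the source and are not reproduced.
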