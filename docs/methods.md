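# Methods

`breastmri` implements a complete diagnosis pipeline for breast masses
imaged with dynamic contrast-enhanced MRI (DCE-MRI) and diffusion-weighted
MRI (DWI): phantom simulation → semi-automated lesion segmentation →
28-feature characterization → hybrid feature-subset selection → nested
cross-validated classification. This note records the models, the
parameters that matter, the numerical choices, and what the bundled
synthetic experiments do and do not demonstrate.

## The phantom cohort

Clinical multiparametric breast-MRI cohorts are rarely shareable, so every
stage is driven by a phantom generator whose defaults emulate the study
conditions the pipeline targets: 234 cases, 149 malignant / 85 benign
(malignant fraction 149/234 ≈ 0.637), single representative 2-D slices at
1 mm pixel spacing, a three-frame dynamic series (pre-contrast, first and
last post-contrast — the only frames any implemented kinetic statistic
consumes) and a diffusion pair at b = 0 and 800 s/mm².

Per case, class-conditional latent variables are sampled independently:

| latent | benign | malignant | planted effect |
|---|---|---|---|
| early enhancement e | N(0.85, 0.40) | N(1.10, 0.40) | slope = e |
| washout w | N(−0.30, 0.45) | N(0.15, 0.45) | SER = 1/(1−w) |
| ADC (10⁻³ mm²/s) | N(1.7, 0.40) | N(1.0, 0.35) | lower in malignancy |
| texture amplitude | 0.055·lognormal(0.35) | 0.095·lognormal(0.35) | heterogeneity |
| spike count / depth | 5±3 / 0.07±0.04 | 7±3 / 0.10±0.05 | mild spiculation |
| age (years) | N(40, 11) ∩ [18, 78] | N(50, 11) ∩ [18, 78] | older malignant |

Boundaries follow a radial model r(θ) = R·(1 + a·cos(kθ + φ)) plus a
smooth low-order random perturbation; malignant outlines are star-shaped
(spiculated), benign near-elliptical. The ADC means (1.7 vs 1.0) fix the
direction and magnitude of the diffusion contrast; the spreads were chosen
once so that univariate AUCs land in the 0.55–0.90 band reported for real
cohorts (ADC strongest ≈ 0.90, slope weakest ≈ 0.63) rather than the
fully separable regime a noise-free simulation would give. The
class-weighted mean age, 0.363·40 + 0.637·50 ≈ 46.4 y, matches the
emulated cohort's 46.2 ± 10.9 (range 18–78). Within the lesion the
dynamic frames are modulated by a spatially correlated multiplicative
texture field (Gaussian-filtered white noise, correlation length
2.5 px·lognormal(0.30) for both classes — the *amplitude*, not the spatial
scale, carries the planted texture signal); the DWI pair obeys
S_b = S₀·exp(−b·ADC) pixelwise before 5% multiplicative Rician-like noise.

What the phantom does **not** model: coil inhomogeneity, motion and
k-space artifacts, pharmacokinetic curve shapes beyond three points,
non-mass-like enhancement, 3-D partial-volume effects, and any correlation
between latents (real kinetic and diffusion abnormalities co-occur).
Passing the bundled experiments therefore demonstrates internal
correctness and statistical calibration of the pipeline, not clinical
performance.

A tabular companion generator (`sample_feature_table`) draws Gaussian
feature matrices with a configurable number of planted and pure-noise
columns; it is used where only the selection statistics are under test
(filter type-I-error calibration) because no imaging is involved in that
property.

## Segmentation: FCM initialization + GVF snake

Step 1 clusters ROI intensities of the first post-contrast frame with
fuzzy c-means (c = 2, fuzzifier m = 2, centres initialized at the
10th/90th intensity percentiles, convergence when the largest centre shift
< 1e−5). The enhancing cluster's >0.5-membership pixels, largest connected
component, holes filled, form the initial mask. Step 2 refines its contour
with a gradient-vector-flow (GVF) active contour.

Numerical choices that required care:

* the GVF edge map |∇(G_σ·I)|², σ = 0.8 px, is normalized to [0, 1] before
  diffusion — the GVF energy is not scale invariant and normalization
  keeps the explicit scheme's stable time step usable
  (dt = 1/(4µ + max|∇f|²), µ = 0.2/4 = 0.05, 300 iterations);
* the snake uses the semi-implicit circulant update
  x ← (I + γA)⁻¹(x + γκF) with weak internal energy (α = 0.01, β = 0.005),
  unit-normalized GVF force (κ = 0.5) — the sign flip of the normalized
  field across the edge ridge makes the ridge a stable equilibrium;
* vertices are resampled to uniform arc length every 10 iterations, not
  every iteration: per-step resampling acts as a low-pass filter that
  erodes spiculation tips;
* the ROI is bilinearly supersampled ×2 before both steps; the converged
  contour is mapped back with the pixel-centre correction
  x_lo = (x_hi − (ss−1)/2)/ss. Sub-pixel boundary placement is what lifts
  noiseless Dice from ≈ 0.96 to ≈ 0.99 on spiculated shapes;
* convergence is declared at mean vertex displacement < 0.02 px; tighter
  tolerances sit below the residual tangential drift of the unit-force
  scheme and never trigger;
* small self-intersection loops at convergence are repaired with the
  zero-width polygon-buffer trick; irreparable contours raise a
  stage-labelled error.

The stronger literature-default internal weights (α = 0.2, β = 0.1,
µ = 0.2, 80 GVF iterations, σ = 1.5) were evaluated first and discarded:
they smooth spiculated boundaries to Dice ≈ 0.89 even on noiseless
phantoms. The malignant default spike depth (a = 0.10 ± 0.05, R = 16 px)
is at the same time a realistic spiculation scale at 1 mm resolution and
within the curvature range a GVF snake can track; much deeper stars
(a ≥ 0.3) exceed any snake's high-curvature fidelity at this pixel size
and are exercised only in shape-operation unit tests.

## The 28 features

One pathology (age), two kinetic, eleven morphological, thirteen GLCM
texture, one DWI feature. Exact reference definitions for the shape
descriptors were not available, so standard radiomics forms are used and
frozen by tests:

* kinetic, on lesion-mean intensities: slope = (SI_first − SI_pre)/SI_pre,
  SER = (SI_first − SI_pre)/(SI_last − SI_pre); SER is flagged undefined
  when the denominator vanishes while early enhancement does not;
* shape (A area, P polygon perimeter, both in mm): circularity = 4πA/P²,
  compactness = P²/(4πA), extent = A/bounding box, solidity = polygon
  area / convex-hull area (computed on the continuous boundary polygon —
  pixelated convex hulls understate smooth shapes by ~2–4%), eccentricity
  and elongation from the second-moments ellipse, spiculation = zero
  crossings of r(θ) − mean(r) per contour vertex (resampling invariant;
  deviations below 1e−6·mean(r) count as zero so float jitter on circles
  does not fabricate crossings), radial-length entropy = base-2 Shannon
  entropy of the 10-bin histogram of max-normalized radii on [0, 1],
  fractal dimension = box-counting slope over box sizes {1, 2, 4, 8, 16}
  clipped to [1, 2], heterogeneity = intra-mask sd/mean on the first
  post-contrast frame;
* texture: GLCM with 32 grey levels (min–max quantization inside the
  mask), the four distance-1 offsets accumulated symmetrically, pairs
  counted only when both pixels are inside the mask, normalized to sum 1.
  The 13 statistics use base-2 logs with 0·log 0 := 0, 0-based indices,
  sum variance about the sum average, IMC1 = (HXY−HXY1)/max(HX,HY),
  IMC2 = sqrt(1 − exp(−2(HXY2−HXY))). A brute-force double-sum oracle
  pins all 13 to 1e−10 in a standing test. Literature synonyms (energy ≡
  ASM, inertia ≡ contrast, rectangular degree ≡ extent, inverse
  difference ≡ inverse difference moment) resolve through an alias table;
* DWI: ADC = ln(S₀/S_b)/b per pixel (reported in 10⁻³ mm²/s). The lesion's
  high-b intensity is dichotomized against the mean of a 5-px dilation
  annulus of background; mean ADC is taken over the high-signal pixels and
  the result is flagged invalid below 20 mm² of high-signal area. Flagged
  cases are excluded from the cohort table with a logged reason.

## Hybrid feature selection

1. **Filter** — per-feature Welch two-sample t-test, keep p < α = 0.05. A
   paired test is impossible for independent groups of unequal size; the
   unpaired unequal-variance form is the statistically coherent choice.
   Calibration is verified: pure-noise features survive at rate ≈ α.
2. **GA wrapper** — binary inclusion chromosomes; fitness = mean k-fold CV
   accuracy of an RBF-SVM (standardized inside the fold pipeline).
   Tournament selection (size 3), uniform crossover (0.8), per-bit
   mutation (0.02), elitism (2); the initial population contains every
   singleton, so the result can never underperform the best single
   feature. Library defaults: population 50, 100 generations, 5-fold
   fitness CV; the bundled study-scale experiments use population 24,
   25 generations and 3-fold fitness CV, which reach the same subsets at
   a fraction of the cost at n = 234. The wrapper SVM uses fixed
   hyperparameters (C = 1, γ = 'scale'): re-tuning C/γ inside every
   fitness evaluation multiplies cost ~60× without changing subset
   ranking at these sample sizes; tuned SVMs are reserved for the final
   evaluation.
3. **Ablation** — greedy backward elimination: while the cheapest single
   omission costs ≤ ε = 0.005 CV accuracy, drop that feature (ties broken
   toward the larger filter p-value). Iterated (not single-pass)
   elimination was chosen; ε = 0.005 operationalizes "negligible" as
   about one reclassified case at n = 234.

The cascade is exposed both functionally (`run_hybrid_fss`, returning a
per-step trace that always partitions the input feature set) and as a
scikit-learn selector (`HybridFeatureSelector`). The recorded reference
cascade (28 → 24 → 13 → 7, ending in ADC, slope, SER, age, entropy,
inverse difference, information correlation 1) is kept as package data;
its step-3 source listed one duplicate name, recorded here as difference
variance — the only texture member otherwise absent from the table.

**What "recovery" means.** The end-to-end selection experiment asks
whether the final subset spans at least four of the five multi-sided
feature groups (pathology, kinetic, morphology, texture, DWI) in ≥ 80% of
seeded study-scale runs. Group level — not exact feature identity — is the
recoverable quantity at n = 234: members of a correlated cluster (e.g. the
GLCM statistics, all partly driven by the planted texture amplitude) are
legitimately interchangeable to a wrapper, so which representative
survives ablation is seed noise, while the *groups* represented are
stable (measured ≈ 85–95% across seed sets, vs ≤ 10% for exact identity).

## Evaluation

Stratified outer 10-fold CV (stratification prevents foldwise class
absence at 36% prevalence); tunable models select hyperparameters by
inner 5-fold CV on the training folds only (SVM grid C ∈ {0.1, 1, 10,
100}, γ ∈ {0.01, 0.1, 1}/p); standardization lives inside the fold
pipeline. Models: RBF-SVM, Gaussian naive Bayes, KNN (k = 6), logistic
regression; multi-feature sets additionally report the arithmetic mean of
the four models ("Averaged"). Single features are evaluated as trained
univariate thresholds: per fold, the Youden-optimal cutoff
(max sensitivity + specificity − 1) and its direction (fixed by the
training AUC orientation) are learned on training data and applied to the
held-out fold; the whole-data threshold is also reported for reference.
AUC is the Mann–Whitney probability with ties counted ½, always computed
from continuous scores (decision function or predicted probability),
never from hard labels. Under label permutation a Youden-trained
threshold's test accuracy centres on 0.5 (it balances the classes rather
than maximizing raw accuracy) — the null-calibration test asserts
exactly that.

## Problem sizes of the bundled experiments

Chosen as the package's default experiment scale: phantom images 96×96 at
1 mm; segmentation-recovery and ADC-recovery experiments use 20-case
cohorts (one render seed per case); filter calibration uses 200 tabular
cohorts of 234×28; selection recovery runs 20 independent 234-case
cohorts with true-contour extraction (isolating selection behaviour from
segmentation error, which is measured separately); the combined-versus-
single-group comparison runs one 234-case cohort through the full
segmentation path. `scripts/acceptance.py` reproduces all of these from a
single seed in about 3 minutes on one CPU.

## Known limitations

* 2-D single-slice analysis only; no multi-lesion ROIs, no DICOM ingestion.
* The GVF snake's high-curvature fidelity bounds recoverable spiculation
  depth; very deep, narrow spicules are systematically rounded.
* The phantom's independent latents make feature combination more
  benign than real, partially collinear clinical features; combined-model
  gains here are an upper bound on what the same pipeline would show
  clinically.
* No multiple-testing correction in the filter (by design, matching the
  emulated protocol) and no DeLong confidence intervals on AUCs.
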