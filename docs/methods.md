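# Methods

This note documents the models, conventions and numerical choices behind
`nawm_radiomics`, in the order data flows through the pipeline.

## Coordinates and containers

Images and masks are 2D numpy arrays indexed `[row, column]`, 0-based,
row-major, with isotropic in-plane spacing.  Patches are extracted in
row-major order.  On disk, images and masks are single-slice NIfTI volumes
(affine = identity scaled by the pixel spacing); ROI class labels travel in
the cohort manifest CSV, not in NIfTI headers.  Real-scan co-registration
is out of scope: the pipeline requires pre-registered baseline/follow-up
pairs and the synthetic generator produces them pre-registered by
construction.

## Synthetic cohorts

Each *case* subject carries an elliptical periventricular-like lesion that
enlarges between baseline and follow-up.  The annulus gained at follow-up
(follow-up WMH ∖ baseline WMH, computed with the same `subtract_masks`
operation the analysis uses) is the dNAWM ROI; its mirror image about the
vertical midline is the non-dNAWM ROI; controls contribute an NWM ROI of
matching annular geometry.  Default geometry: 64×64 images, baseline
radii ≈ 7×6 px, follow-up radii ≈ 12×11 px, giving annuli of roughly
250–400 px — the smallest geometry that honours the ≥100-pixel ROI rule
with a comfortable margin while keeping full-cohort extraction fast.
Geometry jitter is per-subject; a placement that cannot satisfy the
minimum ROI size or that would overlap the mirrored region is retried and
eventually raises a diagnostic `GenerationError`.

### Texture model

Tissue texture is a stationary random field: Gaussian white noise smoothed
with a Gaussian kernel (periodic boundary), standardized, and scaled to
`mean_intensity` / `noise_sd`.  Two further knobs shape heterogeneity:

* `correlation_length` (px) — spatial smoothness.  Shorter correlation
  makes neighbouring pixels less alike, lowering GLCM local-homogeneity
  features such as the inverse difference moment.
* `marginal_flatness` ∈ [0, 1] — a rank-preserving (monotone) interpolation
  of the marginal between Gaussian (0) and uniform (1).  This knob exists
  because all quantized texture features are computed after ROI-local
  min–max binning and are therefore *exactly invariant to affine intensity
  changes*: `noise_sd` alone cannot move histogram Uniformity, and for a
  purely Gaussian field Uniformity and IDM respond in opposite directions
  to the correlation length.  Flattening the marginal spreads the ROI
  histogram across its bins, lowering Uniformity, while shorter
  correlation lowers IDM — together they reproduce the observed joint
  ordering of both features.

Default class parameters (mean 500 a.u., arbitrary scale):

| class     | noise_sd | correlation_length | marginal_flatness |
|-----------|---------:|-------------------:|------------------:|
| NWM       |       36 |                2.2 |              0.00 |
| non-dNAWM |       40 |               2.05 |              0.15 |
| dNAWM     |       52 |               1.25 |              0.90 |

WMH regions add a +300 a.u. intensity boost.  The grading
NWM < non-dNAWM < dNAWM (most heterogeneous) was calibrated once to
reproduce the *qualitative* study behaviour — Uniformity and IDM lowest in
dNAWM with a clear per-cohort significance margin, non-dNAWM only slightly
different from NWM — which yields mean test AUCs near 1.0 for Models 1–2
and around 0.7 for Model 3.  The published AUCs were computed on patient
images that are not deposited; no attempt is made to match their values,
only their ordering.

What the generator does **not** emulate: anatomy, scanner noise spectra,
bias fields, partial-volume effects, registration error, or reader
variability in manual segmentation.  Passing tests therefore demonstrate
correctness of the *pipeline machinery and its statistical behaviour*, not
clinical performance on real FLAIR data.

Everything is a pure function of (spec, seed): per-subject seeds are drawn
from `numpy.random.default_rng(spec.seed)`, and identical specs reproduce
cohorts bit for bit.

## Feature battery

Quantization: 16 equal-width bins over the ROI min–max (configurable); a
constant ROI maps to bin 1.  Gray levels are 1-based in every
index-weighted sum.  Entropies use log base 2 (configurable); 0·log 0 ≡ 0.

* Histogram (13): mean, population SD, Uniformity (Σ pᵢ²), entropy,
  skewness, excess kurtosis, percentiles {5, 10, 25, 50, 75, 90, 95}.
  Skewness/kurtosis of a constant ROI are defined as 0.
* Form factor (5): area, perimeter, compactness 4π·area/perimeter²,
  equivalent diameter, eccentricity of the moment-based best-fit ellipse.
  Perimeter counts exposed pixel edges (10×10 square → 40, single
  pixel → 4), which keeps the isoperimetric bound compactness ≤ 1 on
  digital shapes.
* GLCM (10 features × 18 channels): Energy, Entropy,
  InverseDifferenceMoment, Contrast, Correlation, SumEntropy,
  DifferenceEntropy, SumAverage, ClusterShade, ClusterProminence, per
  (angle, offset) for angles {0°, 45°, 90°, 135°} and offsets {1, 4, 7}.
  Matrices are mask-aware (both endpoints of a pair must lie inside the
  ROI), symmetrized by adding the transpose (non-symmetric mode
  available), and normalized to sum 1.  A zero marginal SD makes
  Correlation undefined; it is reported as 0 with a degeneracy warning.
* RLM (11 features × 18 channels): the Galloway/Chu/Dasarathy–Holder set
  (ShortRunEmphasis … LongRunHighGreyLevelEmphasis, RunPercentage).  The
  feature-name "offset" is interpreted as the *traversal stride* along the
  run direction: offset 1 is the classical maximal-run construction, and
  for stride d the d phase-shifted sub-lattices of each line are traversed
  so that every mask pixel belongs to exactly one run
  (Σ ℓ·r(i,ℓ) = mask pixel count holds for every angle/offset).  The
  semantics of "offset" in the commercial extractor that motivated the
  naming convention are unpublished; the stride reading is a documented
  assumption.

Directional features are aggregated as `AllDirection` (arithmetic mean of
the four angles) and `AllDirection…_SD` (population SD, divisor 4;
sample-SD mode available).  Degenerate sub-computations produce flagged
NaN entries, never silent zeros.  The default battery has 396 named
features (13 + 5 + 10·18 + 11·18); its exact composition is returned by
`battery_feature_names()`.  Whether the commercial battery's printed
total (384) counts the same channels is unknowable from its
documentation, so no attempt is made to match it.  "Uniformity" is read
as the *histogram* energy (a first-order feature), the reading consistent
with its description as a low-order feature.

## Selection cascade

Stage 1 keeps features with p ≤ α (default 0.05) under **both** the
two-group ANOVA (equivalent to the t-test) and the two-sided Mann–Whitney
U test with tie-corrected normal approximation; union mode and
Benjamini–Hochberg correction are available but off by default (the
conservative intersection is the stricter reading of a combined
"ANOVA + MW" criterion; no multiplicity correction matches a single
α = 0.05 criterion).  Constant features are excluded with a warning.

Stage 2 prunes Spearman redundancy at |ρ| > 0.9: repeatedly take the
remaining pair with the largest |ρ| and drop the member with the larger
mean |ρ| against all other remaining features (ties: larger univariate p,
then lexicographically larger name) — fully deterministic.

Stage 3 fits an L1-penalized logistic path (liblinear) with λ chosen by
10-fold stratified cross-validated deviance at the minimum of the mean
(the 1-SE rule is not used); features are standardized to training
mean/unit-SD internally, and λ is reported in the sum-log-loss convention
λ = 1/C.  An empty selection triggers a logged fallback to the stage-2
survivor set downstream.

All stages see training rows only; permuting test rows cannot change the
selection (tested).

## Models and evaluation

One subject-level stratified 7:3 split per cohort is shared by all three
contrasts, so the overlapping case ROIs of Models 1–3 never straddle the
split.  Per-class training counts round half-up, which makes a balanced
51/51 cohort split 72/30 exactly.  Selected features are refit with
unpenalized maximum-likelihood logistic regression (Newton, tol 1e-8);
standardization statistics come from the training rows and are reused
verbatim at prediction.  Complete separation — common under the default
synthetic effect sizes — is detected and flagged, with a weakly
regularized fallback fit rather than unstable raw coefficients.

AUC is the trapezoidal area under the empirical ROC, computed through the
rank (Mann–Whitney) identity with half-tie credit; the default CI is
DeLong's structural-components estimate, with a percentile bootstrap
(2000 resamples) as the alternative.  The operating point maximizes the
Youden index, ties resolved toward the lower threshold.  Hosmer–Lemeshow
uses 10 deciles of risk (quantile bins, ties kept together, degenerate
groups merged with a neighbour) and a χ² reference with groups − 2 df —
appropriate for fitted probabilities; with fewer than three groups the
statistic is reported without a p-value.  ICC is ICC(2,1): two-way random
effects, absolute agreement, single measures, the conventional form for a
fixed pair of readers rating every subject, with McGraw–Wong
F-distribution confidence bounds; reproducibility over a feature battery
is summarized as the per-feature ICC range.

Baseline-characteristics statistics: Pearson chi-square on 2×2 tables
without continuity correction (the convention that reproduces the
published table exactly; Yates correction by flag), pooled-variance
Student's t (Welch by flag) accepting either raw samples or (n, mean, SD)
summaries, and the Mann–Whitney U reported under the min(U, n₁n₂−U)
convention.

## Problem sizes used in tests

The acceptance-style tests run 10 seeded default cohorts (51 + 51
subjects, 64×64 images) for the effect-direction and AUC-ordering checks,
6 null cohorts of 20 + 20 subjects (≈2400 feature-tests) for type-I
calibration, 200 simulations of n = 300 for Hosmer–Lemeshow uniformity,
and ≥100 random patches (≤12×12, ≤8 gray levels) for brute-force oracle
equivalence of every GLCM/RLM feature at 1e-10 relative tolerance.  These
sizes were chosen as the smallest that make the statistical assertions
stable across seeds.

## Known limitations

* 2D single-slice analysis only; no wavelet/filtered-image features; no
  3D texture; no claim of IBSI-certified numerical equivalence with any
  commercial extractor.
* The synthetic generator's effect sizes are a design choice, not an
  estimate from data; absolute AUCs on synthetic cohorts saturate and are
  not comparable to patient-data values.
* The non-dNAWM placement implements the symmetric option only at
  generation time; `mirror_mask` accepts any axis so adjacent placement
  can be composed manually.
* The exact-binomial AUC CI of some clinical packages is not implemented;
  DeLong and bootstrap are.
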