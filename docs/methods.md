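# Methods

## Signal models and units

Three models of the magnitude DWI decay are implemented as pure functions
of the diffusion weighting b (s/mm²):

* mono-exponential (MEM): `S(b) = S0 · exp(−b·ADC)`;
* bi-exponential / IVIM (BEM):
  `S(b) = S0 · [f·exp(−b·D*) + (1−f)·exp(−b·D)]`, with tissue diffusion
  D ≤ pseudo-diffusion D* and perfusion fraction f ∈ [0, 1];
* stretched-exponential (SEM): `S(b) = S0 · exp(−(b·DDC)^α)` with
  heterogeneity exponent α ∈ (0, 1].

The SEM exponent is applied to the full product `(b·DDC)^α`, the canonical
stretched-exponential form. The alternative reading `exp(−b·DDC)^α`
collapses algebraically to a mono-exponential with rate α·DDC and cannot
express intravoxel heterogeneity, so it is rejected.

All diffusivities are carried internally in mm²/s, making `b·D`
dimensionless; report tables apply the conventional ×10⁻³ mm²/s display
scale. The default acquisition is a 12-b-value protocol
(0, 50, 100, 150, 200, 300, 500, 800, 1000, 1500, 2000, 3000 s/mm²) with
per-b averaging counts (NEX) of (1,1,1,1,1,1,1,2,2,3,4,6).

## Voxelwise fitting

**ADC** is the two-point closed form `ln(S(0)/S(1000)) / 1000`. Voxels
with a nonpositive signal at either b, or with S(1000) > S(0) (a negative
implied ADC — noise-dominated), are flagged invalid and excluded from
histograms rather than clamped.

**IVIM** is a joint 4-parameter bounded least-squares fit
(trust-region-reflective, analytic Jacobian) of (S0, D, D*, f), with
bounds D ∈ [0, 3×10⁻³], D* ∈ [0, 0.5], f ∈ [0, 1] (all mm²/s where
applicable) and the ordering D ≤ D* enforced as a validity check.
Initialization is segmented: D and f from a weighted log-linear fit of the
b ≥ 200 s/mm² tail (the perfusion-free regime) and its intercept gap, D*
from a 25-point coarse grid. The segmented start stabilizes the notoriously
ill-conditioned D* estimate; because the optimizer only accepts
cost-decreasing steps, the reported residual norm never exceeds the
initialization's.

**SEM** fits (S0, DDC, α) with α ∈ (0.01, 1], DDC ∈ [0, 10×10⁻³],
initialized at α = 0.9 and DDC at the two-point ADC. With exactly two
positive signals α is unidentifiable and the α = 1 (mono-exponential)
boundary sub-model is solved in closed form.

Residuals are weighted by √NEX by default so b-values acquired with more
averaging count proportionally more; unweighted fitting is available.
Whether the highest shells (b = 2000, 3000) enter the BEM/SEM fits is
configurable via `b_max`; the default uses all 12 b-values.

Degenerate-fit policy: a voxel is invalid when the optimizer fails, when
D* < D, when fitted D* pins at its 0.5 mm²/s ceiling (a noise-chasing
runaway mode, ~2–4% of voxels at SNR 50, whose 100×-typical values would
otherwise dominate VOI means), or when no decay at all is detected
(constant signal). Fitting is deterministic — no random restarts — so
identical inputs yield bit-identical maps, and `fit_volume` is exactly a
voxel loop of the scalar fitters.

No Rician noise-floor correction term is included in any model; the models
are fitted exactly as written above. This is a known limitation at high b
where the noise floor biases magnitudes upward.

## Histogram features

Six statistics per metric over the multiset of valid in-VOI voxel values:
mean, median, 10th and 90th percentile (linear interpolation between
closest ranks), kurtosis and skewness. Kurtosis is Pearson-normalized
(normal = 3) by default — consistent with reported tumour-map kurtosis
values of ~3–4 — and skewness is the classical population third
standardized moment; both are configurable (excess kurtosis,
adjusted Fisher–Pearson skewness) and the conventions in force are
recorded in every output. Values are sorted before accumulation, making
the features exactly permutation-invariant. A zero-variance input reports
skewness 0 and the convention's normal-reference kurtosis with a
degenerate flag; with fewer than 4 voxels the shape statistics are marked
missing. The VOI is always intersected with the fit validity mask and the
resulting voxel count reported for audit.

## Cohort statistics

* **Group comparison**: Shapiro–Wilk at α = 0.05 on both groups gates the
  test — both normal → Welch (unequal-variance) two-sided t-test,
  otherwise two-sided Mann–Whitney U. Welch is preferred over the pooled
  t because the emulated design has unequal group sizes (30/17). Both
  mean ± SD and median ± IQR summaries are always computed. A constant
  group defeats the normality test and routes to the rank test; two
  identical constant groups return p = 1, flagged.
* **ROC**: the empirical AUC is the normalized Mann–Whitney U with ties
  counted ½ (identical to trapezoidal integration of the empirical ROC).
  Scores are oriented so AUC ≥ 0.5 and the orientation is reported. The
  95% CI uses the DeLong structural-components variance. The operating
  point maximizes Youden's J = Se + Sp − 1 over observed values (a 10⁻¹²
  tolerance absorbs floating-point noise in J; ties break toward higher
  specificity, then the higher cutoff); Se, Sp, accuracy, PPV and NPV are
  evaluated at that cutoff with "score ≥ cutoff" calling a subject hard.
* **DeLong test** for correlated AUCs: per-observation structural
  components are computed by midranks; the variance of the AUC difference
  combines their sample covariance matrices across the positive and
  negative groups; the two-sided p comes from the normal reference.
  Degenerate zero-variance comparisons return p = 1 (equal AUCs, flagged).
* **Agreement**: ICC(2,1) — two-way random effects, absolute agreement,
  single measure (pingouin's ICC(A,1)); ICC(3,1) is available. Agreement
  bands follow the conventional touching intervals (0.00–0.20 poor,
  0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 good, 0.81–1.00
  excellent); a value strictly between printed bounds (e.g. 0.205) falls
  in the lower band. Bland–Altman bias is the mean paired difference,
  limits of agreement bias ± 1.96·SD. Identical raters give ICC = 1 by
  convention even with degenerate variance.
* **Multiple testing**: none is applied, matching the emulated analysis
  design; reports annotate the number of features tested (36) so readers
  can judge the family-wise context themselves.

## The synthetic phantom

Each subject is an ellipsoidal VOI (semi-axes 0.30 of the volume shape,
jittered ±20% per axis) inside an otherwise empty volume. Voxelwise
generative parameter fields are smooth random fields: white noise
smoothed by a 3-voxel moving average (renormalized to unit variance),
scaled per class. Normal-family fields vary additively; lognormal-family
fields multiplicatively (the location parameter is then the field median).
A subject-level location is drawn first, then voxel-level variation is
superimposed, and values are truncated to physical ranges.

The default generative truth is bi-exponential per voxel — so BEM recovery
is exactly testable, and ADC/DDC/α maps arise from fitting, mirroring
reality where no single model is "true". A stretched-exponential
generative mode exists for SEM recovery studies.

Noise is Rician: each excitation observes
`sqrt((S + n1)² + n2²), n1, n2 ~ N(0, σ²)` with σ = S0/SNR, and the NEX
magnitudes per b-value are averaged, as in magnitude-domain signal
averaging (background voxels therefore have the Rayleigh mean σ√(π/2)).
The default SNR at b = 0 is 50. All randomness flows from one master seed
via per-subject derived seeds, making cohorts bit-reproducible.

Class calibration targets published soft/hard group summaries. Soft:
D ~ N(0.55, 0.05)×10⁻³ mm²/s; D* lognormal, median 3.74×10⁻³; f lognormal
median 0.25. Hard: D lognormal median 0.52×10⁻³; D* lognormal median
3.52×10⁻³ with a much larger voxel-level spread (log-σ 0.85 vs 0.37);
f lognormal median 0.28. The hard class's heavy low tail of D* — a
substantial fraction of near-avascular voxels with D* approaching D —
is what raises its fitted α upper percentiles: a voxel whose
pseudo-diffusion barely exceeds its tissue diffusion decays almost
mono-exponentially and fits α near 1. This reproduces, mechanistically,
the observed association between hard consistency, low D* percentiles
and high α percentiles. Subject-level scales are set somewhat below the
printed between-subject dispersions because those printed dispersions
also contain fit noise and finite-VOI sampling variability, which the
pipeline re-adds downstream.

What the phantom does *not* emulate: brain anatomy, EPI distortion,
motion, coil sensitivity profiles, necrotic/cystic/calcified inclusions,
partial-volume edges, and spatial correlation between the parameter
fields (e.g. between f and D*). Passing tests therefore demonstrate the
correctness and power of the analysis chain under idealized two-class
structure, not clinical performance.

There is also a desk-scale generator that bypasses imaging entirely,
drawing per-subject feature values directly from per-class Normal(mean,
SD) summaries; it supports closed-form validation of the diagnostic
stage, since the expected empirical AUC of two normal classes is
Φ(Δμ / √(σ₁² + σ₂²)).

## Problem sizes and numerical choices

Simulated validation cohorts use 16×16×10 voxel volumes (VOIs of roughly
200–350 voxels) at the study's group sizes (30 soft / 17 hard), which
gives stable histogram features while keeping full-cohort runs fast;
larger volumes only tighten per-subject percentile estimates. Noisy-fit
calibration uses 1000 voxels at SNR 50; diagnostic-stage validation uses
1000–2000 replicate feature cohorts. Optimizer tolerances are scipy
defaults with at most 400 function evaluations per voxel; grid-oracle
cross-checks in the test suite use iteratively refined exhaustive
searches.

## Known limitations

* D* is intrinsically ill-conditioned; at SNR 50 its median relative
  error is several times that of D, and single-voxel estimates should not
  be interpreted individually.
* The two-point ADC inherits any perfusion contribution between b = 0 and
  1000 s/mm².
* No noise-floor correction: at b = 3000 s/mm² with low SNR all fitted
  rates are biased low, partially offset here by NEX weighting.
* ICC confidence intervals are not propagated into the agreement report
  (point estimates and bands only).
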