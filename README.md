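# dwihist

Multi-b-value diffusion MRI model fitting, whole-VOI histogram radiomics
and two-group diagnostic statistics.

## The problem

Tumour consistency (soft vs hard, e.g. of meningiomas) strongly affects
surgical planning, but is only known intraoperatively. Quantitative
diffusion-weighted MRI offers a non-invasive proxy: the way the magnitude
signal S(b) decays with diffusion weighting b reflects cellularity and
microvascular perfusion. `dwihist` implements the full analysis chain for
discriminating two tumour classes from multi-b-value DWI:

1. **Voxelwise signal-model fitting** of three decay models over a 12-b
   acquisition (b = 0…3000 s/mm²):
   * mono-exponential: `S(b) = S0 · exp(−b·ADC)` (two-point closed form
     over b = 0, 1000);
   * bi-exponential (IVIM): `S(b) = S0 · [f·exp(−b·D*) + (1−f)·exp(−b·D)]`,
     separating tissue diffusion D from pseudo-diffusion D* mixed by the
     perfusion fraction f;
   * stretched-exponential: `S(b) = S0 · exp(−(b·DDC)^α)`, whose exponent
     α ∈ (0, 1] quantifies intravoxel diffusion heterogeneity.
2. **First-order histogram features** (mean, median, 10th/90th percentile,
   kurtosis, skewness) of each parameter map over a whole-tumour VOI.
3. **Diagnostic statistics**: normality-gated two-group tests
   (Shapiro–Wilk gate; Welch t vs Mann–Whitney U), empirical ROC analysis
   with DeLong confidence intervals and Youden-optimal cutoffs, DeLong
   tests for correlated AUC differences, and ICC(2,1)/Bland–Altman
   interobserver agreement.
4. **A seeded synthetic phantom** that simulates labelled two-class DWI
   cohorts (smooth voxelwise IVIM parameter fields inside an ellipsoidal
   VOI, Rician magnitude noise with per-b NEX averaging) calibrated to
   published soft/hard group statistics, so the whole pipeline can be
   exercised and validated end to end without clinical data.

## Worked example

```python
from dwihist import (simulate_cohort, fit_volume, extract_features,
                     merge_records, records_to_frame, analyze_cohort)

cohort = simulate_cohort(n_soft=10, n_hard=10, snr=50.0, seed=7,
                         shape=(16, 16, 10))
records = []
for sub in cohort:
    per_model = [extract_features(fit_volume(sub.dwi, sub.mask, m),
                                  sub.mask, sub.subject_id, sub.label)
                 for m in ("mem", "bem", "sem")]
    records.append(merge_records(*per_model))
table = records_to_frame(records)          # one row per subject
analysis = analyze_cohort(table)           # 36 features tested
for d in analysis.diagnostics:             # the significant ones
    print(f"{d.feature_name:16s} AUC {d.auc:.2f} "
          f"({d.auc_ci_low:.2f}-{d.auc_ci_high:.2f}) cutoff {d.cutoff:.3g} "
          f"Se {d.sensitivity:.0%} Sp {d.specificity:.0%} ({d.orientation})")
```

prints

```
D_p10            AUC 0.87 (0.68-1.00) cutoff 0.000359 Se 80% Sp 90% (lower-is-hard)
Dstar_kurtosis   AUC 0.80 (0.58-1.00) cutoff 13.5 Se 100% Sp 70% (higher-is-hard)
Dstar_mean       AUC 0.88 (0.73-1.00) cutoff 0.00604 Se 90% Sp 80% (higher-is-hard)
Dstar_p10        AUC 0.80 (0.58-1.00) cutoff 0.00149 Se 90% Sp 80% (lower-is-hard)
Dstar_p90        AUC 0.82 (0.63-1.00) cutoff 0.00852 Se 80% Sp 80% (higher-is-hard)
Dstar_skewness   AUC 0.81 (0.59-1.00) cutoff 2.7 Se 100% Sp 70% (higher-is-hard)
alpha_p90        AUC 0.84 (0.65-1.00) cutoff 0.935 Se 60% Sp 100% (higher-is-hard)
f_mean           AUC 0.75 (0.52-0.98) cutoff 0.31 Se 80% Sp 80% (higher-is-hard)
f_p90            AUC 0.77 (0.55-0.99) cutoff 0.436 Se 80% Sp 80% (higher-is-hard)
```

Each line is one feature that differed significantly between the simulated
soft and hard groups: its empirical AUC with a DeLong 95% CI, the
Youden-optimal cutoff in the map's native units (mm²/s for diffusivities),
the sensitivity/specificity at that cutoff, and the score orientation
(whether larger or smaller values indicate a hard tumour). In this
phantom, as in the clinical setting it emulates, hard tumours carry a
heavy low tail of pseudo-diffusion (near-avascular voxels), which raises
their stretched-exponential α upper percentiles — hence `alpha_p90`
(higher-is-hard) and the D* percentile features discriminate.

## Command-line pipeline

The same chain is available as a reproducible four-stage CLI operating on
one working directory:

```sh
dwihist simulate --out work --seed 1 --n-soft 30 --n-hard 17
dwihist fit      --out work --models mem,bem,sem
dwihist features --out work
dwihist analyze  --out work
```

`simulate` writes per-subject NIfTI DWI volumes and VOI masks, a b-value
file and a cohort manifest; `fit` writes per-metric NIfTI parameter maps
with JSON sidecars; `features` produces `features.csv` (one row per
subject, columns `metric_statistic` such as `alpha_p90`); `analyze` emits
group-comparison, diagnostics and DeLong CSV tables plus a JSON report
with embedded provenance. Re-running from the same seed reproduces every
CSV byte-identically (timestamps are isolated to one provenance field).

## Layout

* `src/dwihist/signal_models.py` — forward decay models, acquisition scheme
* `src/dwihist/fitting.py` — voxelwise fitters and map generation
* `src/dwihist/phantom.py` — synthetic cohort generator
* `src/dwihist/histogram.py` — VOI histogram features
* `src/dwihist/stats.py` — group tests, ROC/Youden/DeLong, ICC/Bland–Altman
* `src/dwihist/io.py` — NIfTI/b-value/CSV/JSON readers and writers
* `src/dwihist/cli.py` — pipeline CLI
* `docs/methods.md` — models, conventions, calibration and limitations
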