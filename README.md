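# flowmrd

Validation and post-implementation monitoring toolkit for AI-assisted
flow-cytometry detection of minimal residual disease (MRD) in chronic
lymphocytic leukemia (CLL).

## The problem

Clinical laboratories increasingly pair a trained classifier with human
review to call CLL MRD from 10-color flow cytometry (CD5, CD19, CD20, CD22,
CD38, CD43, CD45, CD200, Kappa, Lambda plus scatter). Deploying such a
workflow safely needs two things the classifier itself does not provide:

1. **Validation statistics** — method comparison against the manual
   reference (binary concordance with exact intervals, Deming regression),
   precision verification (repeatability and within-laboratory variance
   components against upper verification limits), inter-rater agreement
   (accordance / concordance / concordance odds ratio, tests of equal
   sensitivities and specificities), and analytical-sensitivity checks at
   the lower limit of quantitation.
2. **Continuous monitoring** — input-drift / out-of-distribution detection,
   event-level error analysis of classifier-vs-corrected labels,
   hash-verified daily electronic QC, and statistical acceptance sampling
   of reported negatives.

`flowmrd` implements both layers, plus a synthetic event-cloud simulator so
every statistic can be exercised end to end without patient data. It is a
library first (see `examples/`), with a thin `flowmrd` CLI for the one-shot
operations.

## Core methods

- **Drift detection.** Events are prepared (median imputation, frequency
  encoding of declared categorical metadata, standardization), projected
  onto a PCA basis retaining ≥ 65% of reference variance, and reconstructed.
  The sample score is the mean per-event Euclidean reconstruction error
  ‖z − V<sup>T</sup>Vz‖; alerts fire outside the reference mean ± 3 SD, and
  a formal drift event requires ≥ 5 same-day alerts in one direction.
- **Deming regression.** Errors-in-variables fit with slope
  b = [s<sub>yy</sub> − λs<sub>xx</sub> + √((s<sub>yy</sub> − λs<sub>xx</sub>)² + 4λs<sub>xy</sub>²)] / (2s<sub>xy</sub>),
  delete-1 jackknife standard errors, and z-tests for comparing group fits.
- **Acceptance sampling.** Exact hypergeometric single-stage attributes
  plan: the smallest n with P(X ≤ c | N, d\*, n) ≤ 1 − confidence, where d\*
  is the defective count at which the lot first misses the quality level;
  tails are exact integer-arithmetic pmf sums, no approximation.
- **Case calling.** MRD% = clonal events / viable white cells × 100;
  positive requires a ≥ 20-event clonal cluster at or above the LLOQ
  (0.002%); signals between the LOD (0.001%) and LLOQ, or sub-cluster
  populations, are equivocal.
- **Electronic QC.** The full pipeline output is canonically serialized
  (sorted keys, 6 significant digits) and SHA-256 hashed against a
  reference digest frozen at validation.

## Worked example

Deriving the negative-case review plan (`examples/05_acceptance_sampling.py`):

```text
lot N=444, acceptance number c=1
limiting defectives d*=23 (lot quality drops below 95%)
exact minimal sample size: 83
operational sample size (even 6-month split): 84 -> [14, 14, 14, 14, 14, 14] per month
  at d*=23: 0.0470 (<= 0.05)
0 failure(s) in 84: 100.0% confirmed -> ACCEPT
1 failure(s) in 84: 98.8% confirmed -> ACCEPT
2 failure(s) in 84: 97.6% confirmed -> REJECT -> investigate
```

Reviewing 84 of 444 reported negatives (14 per month) with at most one
failure gives 95% confidence that at least 95% of all reported negatives
are truly negative; a second failure rejects the lot and triggers an
investigation.

Binary method comparison (`examples/03_method_comparison.py`):

```text
accuracy       97.5%  (234/240; 95% CI 94.6-99.1%)
sensitivity   100.0%  (129/129; 95% CI 97.2-100.0%)
specificity    94.6%  (105/111; 95% CI 88.6-98.0%)
ppv            95.6%  (129/135; 95% CI 90.6-98.4%)
npv           100.0%  (105/105; 95% CI 96.5-100.0%)
noninferiority vs 97.5%: pass=True (exact p = 0.556)
```

The other examples cover cohort simulation, drift monitoring, precision and
rater agreement, and the error-analysis/QC loop; each prints what it
computes and a line on how to read the numbers.

## Layout

```
src/flowmrd/
  synthcyto.py           synthetic samples, error models, designs, FCS/CSV I/O
  drift_monitor.py       PCA reconstruction-error drift detection
  validation_stats.py    Deming, concordance, precision, agreement, LLOQ
  acceptance_sampling.py exact hypergeometric attributes plans
  error_analysis.py      event confusion, case calling, missed-case reports
  qc_harness.py          canonical digests, daily QC, monitoring log, export
  cli.py                 thin command-line wrappers
examples/                one narrative script per capability
docs/methods.md          models, assumptions, parameter choices, limitations
```
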