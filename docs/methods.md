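# Methods

This note documents the models behind `flowmrd`, the parameters that
matter, the numerical choices, and what the synthetic data can and cannot
show. Nothing here states a result the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cytometry model (`synthcyto`)

**Intensity model.** Each population (polytypic B-kappa/B-lambda, T cells,
hematogones, other white cells, debris, and four clonal phenotypes:
classic CLL, MCL-like, CD5-negative, atypical) is a multivariate Gaussian
on the asinh scale, back-transformed to raw uncompensated intensities
(`raw = sinh(x) · 150`). The asinh-Gaussian shape gives the right-skewed,
heavy-tailed raw distributions real cytometers produce while staying
two-parameter per channel. Channel–channel dependence is a single
exchangeable correlation per template (default 0.1) — enough multivariate
structure for PCA-based drift scoring to be non-trivial, far short of real
spillover structure.

**Templates.** Template locations use a four-level intensity vocabulary
(negative ≈ 0.5, dim ≈ 2.0, moderate ≈ 3.2, bright ≈ 4.2–4.8 asinh units)
chosen to encode the qualitative phenotype contrasts that distinguish the
clonal classes: classic CLL is CD5+/CD200+ with dim CD20/CD22/light chain
and CD43+; the atypical/MCL-like/CD5-negative templates invert one or more
of those axes (moderate CD20/CD22, CD43 negative-or-partial, CD200
negative, moderate light chain). Absolute scales are arbitrary: no public
reference intensities exist for this panel, and the templates are
qualitative reconstructions, not fits to any clinical cohort.

**Composition.** Event counts per class follow one multinomial draw.
Default debris is 3% and doublets 2% of events; doublets are sums of two
random singlet events (coincident raw intensities add). Bone-marrow
specimens carry ~4% hematogones, blood essentially none. The non-clonal
mixture (T ≈ 50–55%, B ≈ 10%, remainder other white cells) reflects
ordinary post-therapy specimens; it is fixed, not configurable per sample,
because the monitoring statistics depend on burden and phenotype, not on
the exact normal mix.

**Randomness.** Every stochastic operation takes an explicit seed
(`numpy.random.default_rng`); there is no hidden global state, and
identical spec + seed reproduces a bit-identical sample.

**What the simulator does not emulate.** Instrument-specific spillover,
day-to-day calibration walk, reagent-lot shifts, acquisition-order
carryover, and genuinely continuous phenotype spectra. Tests passing on
synthetic data therefore demonstrate the *statistical machinery* —
estimators, thresholds, rules, serialization — under the assumed data
shape, not classifier performance on patients.

## Drift detection (`drift_monitor`)

The reference pipeline: per reference sample, one without-replacement
subsample of `n_sub` events (default 10,000; all events when fewer);
pooled subsamples define training medians (imputation), level frequencies
(encoding of declared categorical metadata such as specimen type or
instrument), and standardization means/SDs. Constant features are dropped
with a warning. PCA comes from the SVD of the standardized pooled matrix;
`k` is the smallest component count whose cumulative explained variance
reaches the target (default 0.65). Loadings are made deterministic by
forcing each component's largest-magnitude element positive.

A sample's score is the **mean per-event Euclidean distance** between its
prepared events and their rank-k reconstruction. The mean was chosen as the
simplest aggregate consistent with a single scalar error metric; trimmed or
median variants would damp the sensitivity to small OOD subpopulations that
is the point of the monitor (a 1% clonal burden moves only 1% of events).

The reference error distribution is computed over **per-sample scores**
(one subsample per training sample), not per-event errors, because alerts
are raised on per-sample scores; thresholds are reference mean ± 3 SD
(sample SD, ddof 1). A formal drift event needs ≥ 5 alerts on one calendar
day, all strictly on the same side of the band — mixed directions or
four alerts do not qualify. The absolute threshold values are properties
of the reference cohort; the package never hard-codes them.

Unseen categorical levels at scoring time encode as frequency 0 (maximally
atypical) with a warning. Scoring is deterministic given model, matrix and
seed.

## Validation statistics (`validation_stats`)

**Deming regression.** Closed-form slope with error-variance ratio λ
(default 1, orthogonal); degenerate when s<sub>xy</sub> = 0. Standard
errors are delete-1 jackknife — distribution-free and standard practice for
Deming fits. Group comparisons use two-sided z-tests on the difference of
slopes (intercepts) over the pooled jackknife SEs; a 200-replicate null
simulation in the suite checks the p-values are uniform.

**Sample size.** The quantitative-comparison calculator uses
n = 2 + (1/r² − 1)·((z₁₋α + z₁₋β)/Δ)², inverting the large-sample slope
standard error se(b) ≈ √((1/r² − 1)/(n − 2)) for power 1 − β against a
slope deviation Δ. This is one standard large-sample choice among several;
the function reports its formula alongside the number, and the suite
verifies by simulation that the computed n actually delivers the planned
power.

**Binary concordance.** Accuracy, sensitivity, specificity, PPV, NPV with
exact Clopper–Pearson intervals; ratios with empty denominators are
reported absent rather than zero. The accuracy noninferiority check is the
exact one-sided binomial test; it passes when the observed proportion
reaches the tolerable accuracy outright or the test cannot show it
significantly below.

**Precision.** The crossed design treats each operator × instrument
combination as one run cell (the paper-style design has 2 × 2 cells × 3
replicates = 12 values per sample). Repeatability variance is the pooled
within-cell variance; the within-laboratory variance adds the between-cell
component from the ANOVA method of moments, truncated at zero. Whether
operator and instrument should instead enter as two crossed random factors
is not decidable from a 2×2 layout with 3 replicates; the combined-cell
convention is flagged here and in the result's degrees of freedom
(df_rep = cells·(reps−1), df_wl = cells·reps − 1). Upper verification
limits are one-sided chi-square bounds claimed_sd·√(χ²₁₋α,df / df); an
observed SD above its limit fails verification.

**Qualitative agreement.** Accordance (same-rater replicate agreement)
uses [x(x−1) + (m−x)(m−x−1)] / [m(m−1)] per rater; concordance
(different-rater agreement) averages [xᵢxⱼ + (m−xᵢ)(m−xⱼ)] / m² over rater
pairs; the concordance odds ratio is odds(ACC)/odds(CON), defined as 1 when
ACC = CON (including both 1). Study-level values average per-sample values
within each truth class. The tests of equal rater sensitivities /
specificities are chi-square homogeneity tests on per-rater correct counts,
switching to a Monte-Carlo permutation null (rater totals fixed —
multivariate hypergeometric) when any expected cell is below 5; the exact
statistic of the cited methodology is not reproduced, so these p-values are
an interpretation, checked in the suite against exhaustive permutation
enumeration on small tables.

**LLOQ.** Intra-assay CV = sample SD / mean × 100, strict pass at
CV < 30%: a CV exactly at the threshold fails.

## Acceptance sampling (`acceptance_sampling`)

All tails are exact rational hypergeometric sums (`math.comb`,
`fractions.Fraction`) — exactness is the point at lot sizes of a few
hundred. The limiting defective count d\* is, by default, the smallest D
with (N − D)/N strictly below the quality level (the literal reading of
"at least 95% truly negative"); the ceiling convention ⌈(1−q)N⌉ is also
available and coincides at N = 444, q = 0.95 (both give 23).

The plan search returns the exact minimal n (83 for N = 444, c = 1,
95%/95%) **and** an operational n rounded up to a multiple of the review
periods (default 6), giving 84 = 6 × 14 so the review workload splits into
equal monthly batches. Both numbers are carried on the plan; minimality is
asserted on the exact value, lot evaluation and OC curves use the
operational one. `periods=1` disables the rounding.

## Error analysis and case calling (`error_analysis`)

Event streams binarize clonal-vs-rest: every non-clonal class (polytypic
B, T, hematogones, other white cells, debris, doublets) is negative. The
MRD denominator is viable white cells — debris and doublets are excluded.
Case calling: positive requires both a ≥ 20-event clonal cluster and a
percentage at or above the LLOQ (0.002% at a 10⁶-event denominator);
any non-zero clonal signal that falls short — LOD-band percentages,
sub-cluster populations, or a cluster diluted below the LOD by a very
large denominator — is equivocal; negative means no clonal events. This
makes the call monotone in the clonal count at fixed denominator.

## Electronic QC (`qc_harness`)

Canonical serialization: recursively sorted keys, floats rounded to 6
significant digits, newline-normalized strings, compact JSON; the digest is
SHA-256. Six significant digits keeps the digest stable against
floating-point formatting noise while still catching any single-event label
change or intensity perturbation above 1 part in 10⁶. The "two-stage"
workflow is emulated by a stored correction overlay (event index →
corrected class) applied to the surrogate classifier labels, since no human
reviewer exists at QC time. Pipeline exceptions yield a failing QC record
with the error note — QC never silently passes or crashes. The monitoring
log is an append-only CSV directory (a single-file database backend was
considered and dropped: CSV keeps the store greppable and
dependency-free).

## Problem sizes in the test suite

The suite exercises the estimators at desk scale: reference cohorts of
4–10 samples at 3,000–20,000 events with 1,000–2,000-event drift
subsamples, 200-replicate null calibrations, 400-cohort power checks,
10,000 vectorized precision designs, and a 10⁶-event sample for the rare-
clone count check. These sizes were chosen so each statistical check has
enough resolution for its stated tolerance while the whole suite stays
fast.

## Known limitations

- Template intensities are qualitative; nothing here should be read as a
  fitted model of clinical CLL phenotypes.
- Drift thresholds from synthetic references do not transfer to real
  instruments; refit on local data.
- The equal-rates p-values and the sample-size formula are documented
  interpretations where the underlying publications leave the exact
  statistic unstated (see above).
- Concept drift (label-conditional shift) is out of scope; the monitor
  sees only input-distribution change.
- FCS support is the minimal 3.1 dialect (list-mode float32,
  little-endian, single data segment) the simulator writes; it is not a
  general FCS reader.
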