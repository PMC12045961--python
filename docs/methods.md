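# Methods

## Signal-quality metrics

A trace is a sequence of FHR samples in bpm at a nominal 4 Hz (taken from
the file header; no resampling), optionally with an aligned maternal channel
and a per-sample acquisition-active flag. The analysis window is anchored to
the delivery timestamp: samples in `[delivery − 60 min, delivery]`. Windows
with less than 15 min of recording are *rejected* (a screening outcome, not
an error); exactly 15 min is accepted.

Both artifact fractions share one denominator — the count of
acquisition-active samples in the window — so they are comparable across
episodes and additive as a "missing valid signal" burden:

- dropout = #(active samples with FHR = 0) / #(active samples);
- coincidence = #(active samples with FHR > 0, MHR > 0 and |FHR − MHR| < 5
  bpm) / #(active samples).

A dropout sample is never simultaneously a coincidence sample, and rows
absent from the file (or flagged inactive) are acquisition gaps, not
dropout: dropout is a *recorded* zero. When no maternal channel exists the
coincidence fraction is absent and only the dropout rule can classify
exposure; a monitor-logged coincidence fraction can be supplied instead of
recomputing from channels.

Thresholds use strict inequalities, read literally from their definitions:
exposure is dropout > 0.30 or coincidence > 0.01; exclusion is dropout >
0.90. Boundary values (exactly 30%, 1%, 90%) therefore fall on the
conservative side.

Dose–response bins are equal-count quantiles of `log(dropout + ε)` with
ε = 10⁻⁴ (0.01% on the percent scale), which admits zero-dropout records.
Because the log is strictly monotone, bin membership is identical to
quantile bins on the raw fractions; ε affects only how edges are reported
for all-zero bins. The lowest bin is the reference category.

## Composite outcome

The asphyxia classifier is a disjunction of the criteria listed in the
README; "resuscitation at 10 min followed by NICU admission" is the
conjunction of the two flags. Unknown fields are non-qualifying rather than
errors, so partially documented neonates remain classifiable; a completeness
flag accompanies every classification for sensitivity analyses. A criteria
mask restricts the rule for datasets that do not record every component
(e.g. no NICU events or HIE imaging).

## Elementary statistics

Wilson score intervals (via `statsmodels`) for proportions; Woolf log-scale
CIs and Wald p-values for 2×2 odds ratios, with the Haldane–Anscombe 0.5
correction available behind a flag for zero cells (default: error); the
pooled-variance two-proportion z test; Pearson chi-square with Yates
continuity correction by default (`scipy`). Percentages are rounded to two
decimals at the presentation boundary only.

The OR→NNT conversion uses the overall cohort incidence as the baseline
risk: baseline odds are scaled by the OR, converted back to a risk, and the
reciprocal risk difference is rounded to the nearest integer.

The two-proportion sample-size operation implements the standard
normal-approximation formula (written out in its docstring), with the
Fleiss continuity correction behind a flag. It is a self-contained design
aid and makes no claim to match any particular software's output: published
sample sizes computed with unknown tools are frequently irreproducible from
the textbook formula.

## Doubly robust estimation

The estimand is the exposure–outcome odds ratio under inverse-probability-
weighted regression adjustment (IPW-RA): a logistic propensity model for
exposure given confounders produces ATE weights (exposed 1/e, unexposed
1/(1−e)); a *weighted* logistic regression of the outcome on exposure plus
covariates produces the adjusted OR. Consistency requires only one of the
two models to be correct. No matching is performed. Covariate lists for the
two models are configuration, defaulting to a plausible demographic +
intrapartum set.

Weights are stabilized by the marginal arm probability and truncated at the
1st/99th percentiles of their own distribution by default; both are
standard positivity safeguards and both are configurable and echoed in the
report. Inference uses the robust sandwich variance treating weights as
fixed (bread = weighted Fisher information; meat = outer product of
weighted score residuals), matching common software practice; a percentile
nonparametric bootstrap (default 500 resamples) is available as a
sensitivity mode. With equal weights and no covariates the estimator
reduces exactly to the crude 2×2 OR.

The shared fitting engine is iteratively reweighted least squares with
convergence at max |Δβ| < 10⁻⁸ (cap 100 iterations), a QR-based rank check
that names collinear columns, and quasi-complete-separation detection via
coefficient divergence (|β| > 40 on the log-odds scale). `statsmodels` GLM
serves as an independent cross-check in the test suite, never as the
implementation.

Likelihood-ratio tests compare nested fits on the same records and weights:
statistic 2·(ℓ_full − ℓ_reduced), df = parameter difference (identical
models are allowed and give statistic 0, p = 1). The dose–response analysis
replaces the binary exposure with k−1 quantile-bin indicators (reference =
lowest bin) in the weighted adjusted model and jointly tests them with the
LR test; k defaults to 5. Note the LR statistic on IPW-weighted pseudo-
likelihoods is calibrated here under the fitted weights (verified by
simulation for the unweighted case); balance diagnostics report the
standardized mean difference — weighted mean difference over the pooled
*unweighted* SD, so weighting moves only the numerator — with |SMD| < 0.1
the conventional balance benchmark.

Stage-of-labor subgroup analyses are row filters (presence flags for stage
1 / stage 2) applied before estimation, not separate estimators; no
within-window stage attribution is attempted.

## Missing data

BMI is modeled as the single incomplete covariate. Imputation is Bayesian
normal linear regression on configured predictors including exposure and
outcome (congeniality): per imputation, the residual variance is drawn from
its scaled inverse-chi-square posterior and coefficients from their
conditional normal, then missing values are filled with the linear
predictor plus Gaussian noise. Observed values are never altered; m = 20 by
default (comfortably above the ~6.3% missingness fraction). Pooling follows
Rubin's rules; degrees of freedom use the Barnard–Rubin small-sample
formula when a complete-data df is supplied and the classical large-sample
rule otherwise. Predictive-mean-matching and general chained equations are
out of scope.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is validated.
Covariates use coarse, documented approximations of a term-labor cohort:
age ~ N(32, 4.5²), BMI ~ 24·exp(N(0, 0.18²)), gestation ~ N(39.4, 1.3²)
truncated at 36 weeks, parity/onset/anesthesia/meconium Bernoulli at
realistic rates, birthweight ~ N(3380, 450²) g. Exposure is drawn from a
logistic model on the covariates (BMI the dominant shared cause; effects
listed in `DEFAULT_CONFOUNDER_EFFECTS`) with its intercept calibrated by
root finding to a target prevalence of 18.6%; the outcome likewise, with
the specified true exposure log-OR and intercept calibrated to a 2.67%
incidence. Neonatal outcome fields are generated to satisfy the composite
rule exactly when the outcome label is positive (cord pH route 55%, Apgar
15%, HIE/cooling 15%, resuscitation+NICU 15%).

Traces: FHR fluctuates as an AR(1) (φ = 0.97) around a subject baseline in
110–160 bpm (kept ≥ 30 bpm above the maternal baseline in 70–100 bpm so
accidental coincidence is rare), quantized to 0.25 bpm. Dropout is a
two-state Markov chain with 5 s mean dropout sojourns and stationary
occupancy equal to the assigned target, reflecting the clustered,
short-segment character of real dropout; coincidence episodes (2.5 s mean)
overwrite FHR with MHR ± < 5 bpm. Exposed episodes draw dropout targets in
0.34–0.85 (80%) or coincidence targets in 0.02–0.05 (20%); unexposed
episodes sit clear below both thresholds. The margins absorb Markov
sampling noise, though near-threshold crossover remains possible — as it is
for a real monitor — so pipeline tests check class agreement within a few
percent rather than exactly. The generator returns the *realized* fractions
counted from the emitted arrays, making the round-trip against the
signal-quality module an exact identity. A configurable fraction of
episodes is emitted too short (< 15 min; 5%) or with > 90% dropout (2%) to
exercise the screening filters. BMI missingness is MAR by default (driven
by age and parity, intercept calibrated to 6.3%), with MCAR available for
the sensitivity contrast.

What the generator does *not* emulate: FHR morphology (accelerations,
decelerations, contraction coupling), labor-stage dynamics within the
window, measurement error in covariates, or unmeasured confounding beyond
the specified covariate set. Passing tests therefore demonstrate the
statistical machinery — not that real CTG dropout causes asphyxia, nor that
real confounding is as well-behaved as the simulated kind.

## Validation choices and problem sizes

Parameter recovery runs 200 replicates of n = 20,000 cohorts at a true OR
of 1.47 (|mean log-OR bias| < 0.05, CI coverage 92–98%); the
double-robustness contrast drops BMI from one or both models (100
replicates per arm) and expects small bias under single misspecification
but not dual; LR-test type-I error uses 2,000 null replicates of n = 8,000
(large enough for the asymptotic chi-square reference at a ~10% event
rate); Wilson coverage uses 20,000 simulated proportions per (p, n) cell
over p ∈ {0.01, 0.027, 0.1} × n ∈ {500, 5000, 32000}; the signal round-trip
checks 1,000 full-hour traces. These sizes keep the whole suite to a couple
of minutes on one CPU while leaving Monte-Carlo noise well inside the
asserted bands.

## Known limitations

- Only a single incomplete covariate is supported by the imputation module.
- The sandwich variance treats estimated weights as fixed, which is mildly
  conservative for the ATE in theory; the bootstrap mode relaxes this but
  does not re-estimate the propensity per resample.
- The dose–response model conditions on bins estimated from the analyzed
  cohort; edge uncertainty is ignored.
- Exposure classification near the 30%/1% thresholds is sensitive to
  sampling noise in short recordings, in the package as in practice.
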