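# Methods

## Labelling model

AKI detection uses the creatinine arm of the KDIGO definition only.
Both criteria are inclusive (≥):

* **absolute**: sCr(t) − min{sCr(u) : t − 48 h < u ≤ t} ≥ 0.3 mg/dL,
  with the rolling minimum restricted to in-ICU measurements of the
  same admission (pre-ICU draws never enter the window);
* **ratio**: sCr(t) ≥ 1.5 × baseline for t within 7 days of ICU
  admission.

"Day d" is the 24-hour block [24·(d−1), 24·d) anchored at the ICU
admission timestamp, not a calendar day, so day-1 length does not
depend on admission time. The comparator for the 48-h criterion is the
rolling minimum; a day-level minimum is a plausible alternative
operationalisation, but rolling-min is the standard one and is what the
exhaustive O(n²) test oracle implements as well. Co-timed measurements
are inside each other's windows (the window is u ≤ t), which matters
for duplicate laboratory timestamps. The first firing time defines the
detection day; if both criteria first fire at the same instant the
label records "both".

The detection engine (`kdigo.detect_aki`, monotonic-deque sliding
minimum) is verified against an independent brute-force pairwise scan
(`detect_aki_oracle`) on tens of thousands of fuzzed series; the oracle
exists only for tests.

## Baseline estimators

The two first-24h methods use the minimum day-1 creatinine; the
formula-screened variant additionally computes the MDRD backward value
and uses it *only* to flag day-1 AKI for exclusion (an explicit
two-stage result carrying both values). The four window methods
aggregate (mean or min) outpatient creatinine over [180, 7] or [180, 0]
days before ICU admission and fall back to the MDRD backward value iff
the window is empty. A draw d days pre-admission is in window [a, b]
iff b ≤ d ≤ a; "0 days before" admits same-day draws taken strictly
before ICU admission, and in-ICU measurements are never window
candidates. Duplicate timestamps are kept as a multiset.

The backward formula is implemented with the published exponent −0.887,
which is *not* the exact algebraic inverse of the forward creatinine
exponent (−1/1.154 ≈ −0.8666). Consequently the forward/backward round
trip lands near, not exactly at, 75 ml/min/1.73 m² (within 0.7 over
ages 18–90; 75.39 at age 60, female). The discrepancy is retained
deliberately — fidelity to the published constants over algebraic
purity — with the exact inverse available via
`backward_mdrd(..., exact_inverse=True)` for sensitivity analysis.
CKD-EPI (2009, creatinine, no race coefficient) is a model input
feature only and never participates in labelling.

## Synthetic ICU generator

The generator emulates the structure, not the physiology, of an ICU
EHR extract. Per subject: a piecewise-constant true baseline
creatinine (log-normal across subjects, median 0.9 mg/dL, σ = 0.30 on
the log scale, floored at 0.3) plus i.i.d. Gaussian measurement noise
(default sd 0.05 mg/dL). AKI trajectories are step rises planted on a
target day with a ≥ 4·sd margin above the chosen criterion's threshold,
so noise cannot de-flag them and, with noise disabled, KDIGO labelling
against the true baseline reproduces the latent truth table exactly —
the generator's central testability property. A ratio-sized step
usually also clears the 0.3 mg/dL absolute threshold (any 0.5·b step
with b ≥ 0.6 does), so the planted "mode" records which criterion the
trajectory was sized for rather than an exclusive firing; planting
strictly-one-criterion trajectories is arithmetically impossible for
most baselines.

Whether an admission receives a trajectory follows a logistic risk
model on age, chronic kidney disease, invasive ventilation, sepsis and
the true baseline, with the intercept bisection-calibrated so the mean
event probability equals the configured rate — the realised prevalence
is then binomial around the target, and downstream classifiers have
genuine covariate signal. Admissions destined for day-2/3 AKI carry a
small day-1 creatinine "prodrome", capped strictly below both criteria
margins (min(0.3, 0.5·b) − 4·sd − 0.02), mirroring the clinical
observation that first-day creatinine features dominate AKI models.

Default rates reproduce the regime the benchmark targets: 17.32%
day-2/3 AKI, 28.87% day-1 AKI (excluded downstream), 64.19% of
admissions without any pre-ICU creatinine history, and per-variable
missingness that places albumin (68.37%), bilirubin (50.85%), globulin
(98.69%) and thrombin (99.83%) above the 20% filter. Creatinine
sampling frequency is a parameter (default 3/day on days 1–3, 1/day on
days 4–7) since no canonical value exists. Missingness is applied at
the admission level (all events of a variable removed for a Bernoulli
subset of admissions) because downstream aggregation is per-admission;
day-1–3 creatinine is exempt so the inclusion rule stays satisfiable.

What the generator does **not** emulate: physiological coupling between
non-creatinine variables and AKI beyond the shared risk score,
treatment effects, urine-output-driven AKI, informative missingness,
and calendar-time structure. Passing tests therefore demonstrate the
pipeline's correctness and internal consistency, not clinical
performance on real ICU data.

## Cohort construction

Exclusion cascade, in fixed order with a per-step audit: age ≥ 18 →
first ICU stay per patient → no maintenance renal replacement therapy →
creatinine present on each of days 1, 2 and 3 → no day-1 AKI. The order
is a convention (counts per step are logged so order-dependence is
visible). The outcome is AKI *first detected* on day 2 or 3.

Features are first-24h min/max per continuous variable, mean urine
output, binary history flags, one-hot ethnicity (no reference category
dropped), and CKD-EPI eGFR computed from the **minimum** day-1
creatinine (the choice of day-1 summary feeding eGFR is a convention;
minimum matches the baseline definitions' conservatism). Columns with
strictly more than 20% missingness are dropped before imputation
(two-stage); the chained-equations imputer runs in single-imputation
mode and, like the min–max scaler, is fitted on the training partition
only. Values outside the training range at inference are clipped to
[0, 1], keeping the stated feature-range contract. Leakage guards are
asserted by permuting/corrupting test rows and requiring byte-identical
fitted artifacts.

## Models, calibration, comparison

60/20/20 stratified split. Hyperparameters are tuned by mean 5-fold
cross-validated f1 with minority-class duplication to 1:1 inside each
fold's training part only; the winner is refit on the up-sampled full
training partition. The gradient-boosting search space includes a
configuration mapped from published leaf-wise hyperparameter names
(num_leaves → max_leaves with loss-guided growth, min_child_samples →
min_child_weight) alongside conservative depth-wise settings; the
perceptron is single-hidden-layer, sized by the same CV objective.

Calibration is a Platt sigmoid fitted on validation scores (monotone,
hence AUC-preserving); isotonic is available behind a flag. An
anti-monotone or degenerate fit falls back to an identity map with a
warning. The decision threshold maximises f1 over all distinct
validation probabilities, ties broken toward the larger threshold.

Metrics: rank-based AUC with tie midpoints; precision/recall/f1 with
the 0-on-zero-denominator convention; ECE over 10 equal-width bins
(configurable); Brier score; calibration slope as the ML slope of
outcome on logit(p) with probabilities clipped to [1e−6, 1−1e−6].

The cross-baseline comparison bootstraps f1 on the test set. The
resampling scheme is 500 with-replacement resamples at full test-set
size; an alternative reading (fixed 500-record subsets) is exposed via
`ComparisonConfig.subsample_size` since the sampling unit is genuinely
ambiguous. Groups are compared by one-way ANOVA and Tukey's HSD at
α = 0.05; under identical groups the familywise false-flag rate is
verified to stay at the nominal level over 200 simulated repetitions.

## Attribution

The value function is the marginal (interventional) expectation: v(S)
is the mean model output over a background sample (training partition,
seeded subsample capped at 1000 rows in pipeline use) with the features
in S fixed to the audited instance's values. Break-down reports give
sequential conditional contributions for one ordering; Shapley reports
average them over uniformly random orderings (default 25; audits use 10
randomly selected false positives). Additivity (intercept + Σ
contributions = prediction) holds to numerical tolerance by
construction and is asserted to 1e−8; for ≤ 5 features the ordering
average is verified against an independent subset-enumeration oracle.

## Problem sizes and numerical choices

Test and acceptance runs use 2000-patient synthetic cohorts (≈ 2160
admissions, ≈ 1300 after exclusions), 500 bootstrap resamples, 10,000
fuzzed series for oracle equivalence, 10⁵ simulated outcomes for slope
recovery and 200 repetitions for the Tukey null — sizes chosen so every
statistical check has conventional power while the full suite stays in
the minutes range. All randomness flows from explicit integer seeds
(numpy `default_rng` / `SeedSequence`); fixed seeds give byte-identical
bundles, splits, fits and bootstrap vectors. Degenerate cases are
handled explicitly: zero-variance feature columns scale to 0 with a
warning, constant classifiers get an identity calibration map and an
undefined (flagged) calibration slope, single-class label sets make AUC
undefined rather than silently 0.5.

## Known limitations

* Synthetic realism is deliberately minimal (see generator section);
  absolute metric values on synthetic cohorts are not comparable to
  values on real ICU data.
* The day-1 exclusion under an *estimated* baseline differs from the
  planted day-1 rate by construction — that discrepancy is the object
  of study, so only truth-baseline labelling recovers generator rates.
* Multiple-imputation variance pooling, urine-output criteria, AKI
  staging and recurrent episodes are out of scope.
* The CLI covers simulation, labelling, equations and the end-to-end
  comparison; attribution audits are library-level
  (`akibench.explain`).
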