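# Methods

## Model and estimation

The package implements the dichotomous Rasch model,
P(X_vi = 1) = exp(θ_v − δ_i) / (1 + exp(θ_v − δ_i)), with all locations in
logits. Item calibration uses **conditional maximum likelihood** (CML): the
likelihood is conditioned on each person's raw score, which is sufficient
for θ, so person parameters drop out and the item estimates do not depend
on the ability distribution of the calibration sample. This "sample-free"
property is what justifies treating a calibrated bank as a frame of
reference into which other instruments can be anchored.

The conditional likelihood is expressed through elementary symmetric
functions (ESFs) γ_r of the item easinesses ε_i = exp(−δ_i). ESFs are
computed with the sum recursion carried out entirely in log space
(`logaddexp`); with 57 items a naive product representation overflows, the
log-space recursion is stable for any bank size used here. Missing data are
handled exactly under ignorable missingness by grouping persons into
distinct administered-item patterns and evaluating one ESF table per
pattern; persons with extreme raw scores (0 or maximum on their pattern)
contribute no conditional information and are excluded from the likelihood
automatically.

Optimisation runs L-BFGS on an analytic gradient (observed minus expected
item scores, the expectation requiring single-deleted ESF tables) followed
by damped Newton steps with the exact conditional information matrix
(pairwise-deleted ESFs) until the maximum absolute score residual falls
below 1e-6; non-convergence raises an error carrying the final gradient
norm. Identification: with no anchors the free difficulties are constrained
to sum to zero; with anchors the anchored items pin the frame and the free
items are unconstrained. Items never co-administered with the rest of the
design (or with any anchor) raise a linkage error rather than returning an
unidentified solution.

Standard errors come from the inverse of the conditional information
matrix: the plain inverse of the free block when anchors fix the frame, and
the inverse restricted to the sum-to-zero subspace (equivalently the
Moore–Penrose pseudo-inverse of the singular full matrix, computed via an
explicit orthonormal basis for numerical safety) for free calibrations.

## Person measures and score-to-measure tables

Abilities are maximum-likelihood estimates given the calibrated
difficulties: θ solves Σ_i P(θ, δ_i) = r by safeguarded Newton (bisection
fallback on a bracket, convergence 1e-8, deterministic), with
SE = 1/sqrt(Σ P(1−P)). Extreme raw scores have no finite MLE; they receive
the conventional adjusted-score extrapolation, solving the same equation
for r = ε or K − ε. **ε defaults to 0.3 and is exposed** (`extreme_epsilon`)
because different Rasch packages use different conventions and users may
want to match existing output. Score-to-measure tables evaluate every raw
score 0..K; θ is strictly increasing in the raw score and the SE profile is
U-shaped (most precise near the centre of the item set).

## The 0–100 transform

The reporting transform is the linear map fixed by two anchor points:
0 logits → 50 (the centre of a sum-to-zero calibrated bank) and the
zero-raw-score extrapolated measure → 0. Hence slope = 50/|θ(0)| and
value = 50 + slope·θ, clamped to [0, 100]; 2SE values propagate with the
same slope. The maximum raw score is reported as 100.00 by convention —
the interior linear rule would give less than 100 at the top extrapolated
measure, and the endpoint convention is applied explicitly rather than
inferred. These choices reproduce the published conversion-table rows this
design was reverse-engineered from (interior rows to ≤ 0.05 on the 0–100
scale given 2-decimal inputs).

## Crosswalks

Legacy instruments are placed in the common frame by anchored calibration:
shared items fixed at bank difficulties, remaining items estimated around
them. Conversion tables are aligned by nearest logit location: each legacy
raw score is matched to the reference row minimising |θ_legacy − θ_ref|,
with ties broken toward the lower reference score (conservative: never
overstates ability). Matching is provably monotone for sorted tables and
is validated as such. Export renders one row per reference raw score with
per-instrument columns; reference rows with no matching legacy score stay
empty, and in the (rare) case of two legacy scores sharing a row the cells
are semicolon-joined so the mapping round-trips.

## Diagnostics

All residual-based diagnostics exclude extreme persons (their residuals are
degenerate). Standardized residuals are z = (x − P)/sqrt(P(1−P)).

* **Item fit residuals.** The outfit mean-square u_i = mean(z²) is mapped
  to an approximate N(0,1) scale with the Wilson–Hilferty cube-root
  transform, using the model-implied variance of u_i (from the Bernoulli
  kurtosis of z²). The commercial implementation this mirrors does not
  publish its exact formula; this standardisation is a documented,
  reproducible approximation targeting the same ±2.5 interpretation.
  Items with fewer than 10 responders are flagged low-n.
* **Chi-square.** Persons are split into G equal-count ability classes
  (G = 5 by default, configurable; there is no canonical value and results
  are reported with the class count used). χ² = Σ_g (O−E)²/V with df =
  G_eff − 1; classes with numerically zero variance merge into a
  neighbour. Bonferroni divides by the item count of the analysis at hand,
  not across instruments.
* **DIF.** Two-way fixed-effects ANOVA (type-II sums of squares, so
  unbalanced or empty subgroup × class cells are handled by the general
  linear model) of residuals on subgroup and class interval, run separately
  per grouping factor (diagnosis; gender). Main effect = uniform DIF,
  interaction = non-uniform DIF.
* **Local dependency.** Pairwise-complete residual correlations flagged
  above mean + 0.20 (the relative cut-off); constant residual vectors are
  skipped with a warning.
* **Dimensionality.** Smith's method: PCA of the residual correlation
  matrix, items split by the sign of their first-component loading, person
  abilities re-estimated from each subset with bank difficulties held
  fixed, and t = (θ⁺ − θ⁻)/sqrt(se⁺² + se⁻²) computed per person; the
  percentage with |t| > 1.96 supports unidimensionality when ≤ 5%. An
  all-one-sign loading pattern is reported as a degenerate split, not an
  exception.
* **Reliability.** PSI = (V − M)/V with V the person-measure variance and
  M the mean squared SE, computed with and without extreme persons.

## Synthetic cohort generator

The generator defines the study conditions the pipeline is tested under:
360 assessments in four diagnostic groups with normal within-group
abilities — HC n=87 (mean 0.84, SD 0.95), SCD n=167 (0.75, 0.85), MCI n=52
(0.23, 0.84), AD n=54 (−0.33, 1.31) logits — and a 57-item bank: CBT 14
and DST 12 items on wide ranges (≈ −6 to +7) with two interior gaps each,
RAVLT 15 and WLL 10 items compact around 0 (≈ −1.7 to +1.8), MMSE memory 6
items in between. Difficulties are drawn deterministically from the seed on
stratified grids over the gapped support, reproducing the published
per-instrument ranges and targeting structure without fabricating
unpublished per-item values. Whole-instrument missingness follows the
cohort's pattern: 41 assessments missing all RAVLT items, 88 SCD
assessments missing WLL and MMSE, 2 AD assessments missing DST; the rules
never leave a person with zero administered items. Normality within group
is a minimal assumption — only means and SDs are specified by the design.

What the generator does **not** emulate: serial-position (primacy/recency)
dependence within word lists, practice effects across visits, age or
education effects on ability, and polytomous scoring. Passing tests on
synthetic data therefore demonstrate correctness of the estimation and
diagnostic machinery under the Rasch model with realistic targeting and
missingness — not robustness to the response-process violations real word
lists exhibit.

`inject_violation` provides positive controls: a group-specific difficulty
shift (DIF), probabilistic response copying (local dependency), a
correlated second ability driving an item cluster (multidimensionality),
and coin-flip responses (misfit).

## Numerical and design choices

* Extreme screening iterates person and item screens to a fixed point
  (removing an all-pass item can create a new zero-score person); extreme
  items are excluded from estimation while extreme persons are retained for
  extrapolated measures.
* Ability solver bracket [−10, 10] logits, widened when needed; all
  iterative routines are deterministic.
* CSV dialect: UTF-8, comma-separated, header mandatory; missing written as
  empty cells, `""`/`"NA"` both accepted on read; logits written with six
  decimals; `#` lines carry run metadata (configuration hash and seed), so
  identical configurations yield byte-identical files.
* Problem sizes in the test suite — recovery and calibration replicates at
  n = 500 persons × 20 items, power checks over 10 cohorts, type-I checks
  over 20 — were chosen so Monte-Carlo error is small relative to the
  tolerances being checked while the whole suite stays fast to run.

## Known limitations

* CML differs in finite samples from the pairwise estimator used by some
  commercial Rasch software; calibrations agree within quoted
  uncertainties, not digit-for-digit.
* The extreme-score extrapolation and fit-residual standardisation are
  conventions; tables produced with other conventions will differ slightly
  in the extreme rows and flag counts.
* DIF power depends strongly on item targeting: shifts on items far from
  the cohort's ability range are intrinsically hard to detect.
* Only dichotomous items are supported; polytomous response categories and
  testlet (subtest) models are out of scope.
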