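# Methods

## Scope and model

`rrtuplift` estimates the individual treatment effect (ITE) of renal
replacement therapy on 28-day survival in sepsis-associated AKI from a
flat observational cohort table, using the class-transformation reduction:
the label `Z = 1{treated ∧ survived} ∨ 1{untreated ∧ died}` turns uplift
estimation into a single probabilistic classification, and
`uplift = 2·P(Z=1|X) − 1` equals the survival-scale benefit
`P(S=1|T=1,X) − P(S=1|T=0,X)` exactly when `P(T=1|X) = 1/2`.

That identity is the method's central assumption.  The pipeline arranges
it by 1:1 propensity matching before fitting; the model constructor warns
whenever the training arms are unequal, because the identity then fails
and the score becomes a biased (though often still rank-informative)
estimate.  Other standing assumptions: the outcome is fully observed at
28 days (no censoring), treatment is a single binary decision (no timing
or dose), and all confounders are among the measured covariates —
matching removes only *measured* imbalance.

## Synthetic cohorts and what they emulate

The generator (`simulate.py`) produces cohorts with the three structural
features the analysis must handle, each controlled by a `SimConfig`
field:

* **Confounded assignment.**  `logit P(T=1|X) = α +
  confounding_strength · severity(X)`, where `severity` is the
  standardized mean of signed z-scores of SOFA, creatinine, lactate and
  −urine output (rescaled to unit variance), and α is calibrated by
  bisection so the marginal treated fraction hits
  `treat_fraction_target`.  Defaults: n = 8,289 stays, treated fraction
  591/8289 ≈ 7.1%, confounding_strength = 1.0 log-odds per severity SD —
  sicker patients are visibly more likely to be treated, and the
  severity covariates show pre-matching |SMD| ≈ 0.3–0.5.
* **Outcome model.**  Control-arm death probability
  `expit(baseline_mortality_logit + mortality_severity_coef · severity)`
  with defaults −1.55 and 0.9, giving ~20% overall 28-day mortality and
  making naive treated-vs-control contrasts confounded.
* **Heterogeneous benefit.**  `τ(X) = effect_intercept + Σ coef_v ·
  z_v(X)` on the survival-probability scale, with defaults
  `+0.05 − 0.06·z(log urine output) + 0.05·z(log lactate) +
  0.04·z(log WBC)`: benefit concentrated in oliguric, hyperlactataemic,
  high-WBC patients, averaging ≈ +5 survival points — the magnitude of
  the matched-cohort mortality contrast (32.3% vs 39.3%).
  `p_death_treated = clip(p_death_control − τ, 1e−4, 1−1e−4)`; clipping
  is counted and warned about (≈4% of records under defaults, mostly
  low-risk patients whose benefit cannot be realized).

Covariate marginals default to the non-treated arm of a large published
S-AKI ICU cohort: log-normal for skewed labs and urine volumes
(parameters matched to reported medians/IQRs or mean±SD via the
log-normal moment equations), normal for vitals, integer-categorical for
qSOFA and KDIGO stage.  Units are fixed once — creatinine and glucose in
mg/dl (converted from SI where the source reported SI: 122.88 µmol/l →
1.39 mg/dl; 7.63 mmol/l → 137.3 mg/dl) — because the source table mixed
unit systems between its pre- and post-matching columns.

All draws descend from a single `seed` through `SeedSequence` spawning
(one sub-stream each for covariates, assignment, outcomes), so cohorts
are bit-reproducible.

**What the generator does not emulate:** longitudinal trajectories and
time-varying treatment decisions, unmeasured confounding, competing
risks or censoring, missing data (columns are complete; the imputation
path is exercised only if a caller supplies NaNs), and correlated
covariates beyond what the shared severity/effect indices induce —
marginals are drawn independently.  Passing tests therefore show the
*estimators* behave correctly under the stated structure; they do not
show that real EHR data satisfies that structure.

## Cohort construction

KDIGO staging is a declarative threshold table (stage 1: SCr 1.5–1.9×
baseline, or ≥0.3 mg/dl rise in 48 h, or urine output <0.5 ml/kg/h over
6 h; stage 2: 2.0–2.9× or <0.5 over ≥12 h; stage 3: ≥3.0×, SCr ≥4.0
mg/dl, RRT initiation, <0.3 over 24 h, or anuria ≥12 h), overridable per
call; the stage is the maximum of the creatinine- and urine-based
stages.  Baseline-creatinine definition is the caller's responsibility.

Filters retain sepsis-3 flag = true, highest KDIGO stage ≥ 1, first ICU
admission, age ≥ 18, no ESRD, potassium ≤ 6.5 mmol/l (strict: 6.5 itself
is retained), in that reporting order.  Filters are conjunctive, so the
retained set is order-invariant; only per-filter attrition counts depend
on order.  Cohorts carry both a baseline `kdigo_stage` and
`kdigo_stage_highest`; filtering uses the highest stage, which is why
stage-0 *baseline* rows can legitimately appear inside an analysis
cohort.

## Matching

Propensity is a main-effects logistic regression (statsmodels `Logit`)
of treatment on all baseline schema covariates; constant covariates are
dropped with a warning and a covariate that perfectly separates the arms
is reported by name.  Matching is greedy 1:1 nearest-neighbor without
replacement on |Δ logit(PS)|: treated processed in descending propensity
(ties → lower id), each taking the closest unmatched control (ties →
lower id).  The default caliper is 0.2 × SD of the logit propensity, the
common convention; it is configurable and `None` disables it.  The
protocol is fully deterministic, which the tests exploit by checking it
against a literal reference implementation.

SMD uses the two-sample form with sample SDs for continuous variables
and the binomial-variance form for binary ones, reported as absolute
values; a zero pooled variance is defined as SMD 0 when the means agree
and an error otherwise.

## Uplift model

Default learner: gradient-boosted trees (xgboost, 300 trees, depth 3,
learning rate 0.05, subsample 0.8, single thread, seeded) — chosen
because per-observation additive attributions of a nonlinear learner are
part of the analysis.  `learner="logistic"` gives a standardized
penalized logistic regression.  Missing covariates are median-imputed
with medians computed on the development cohort only.  Predicted
probabilities are clipped to [1e−6, 1−1e−6] before the 2P−1 transform so
overfit trees cannot emit spurious ±1 benefit.  The pipeline performs a
single fit — no tuning loop — on the matched development cohort (70% of
matched pairs, stratified by arm) and scores the held-out validation
cohort.

Feature attributions use xgboost's native TreeSHAP (`pred_contribs`),
which is exactly additive on the log-odds scale up to float32
accumulation (residuals ≲ 1e−5; the tests allow 1e−4); the logistic
learner's attributions are exact linear contributions.

## Qini conventions

* `y = 1` in the qini formula is *observed* 28-day survival among the
  selected fraction — a qini on predicted outcomes would evaluate the
  model against itself.
* Top-φ selection takes `ceil(φ·N_arm)` per arm; ranking ties are broken
  by stable sort then ascending id, so curves are reproducible even with
  heavily tied rankers like KDIGO stage.
* The random line is the chord from (0, 0) to (1, Q(1)); AUUC is the
  trapezoidal area between curve and chord on the φ grid (default
  deciles, configurable).  Q(0) = 0 by convention.
* Clinical comparators default to higher-score-ranks-first; the
  direction is configurable.

A practical warning demonstrated in the README: at a few hundred
validation patients a single-split AUUC has a standard error comparable
to its plausible magnitude, so its sign is not stable across seeds.
Conclusions about ranking quality in the tests therefore rest on
ground-truth correlation and on AUUC at larger, randomized samples.

## Benefit profiling

The test-selection rule is explicit because "as appropriate" is not
operational: binary variables get Yates-corrected chi-square; continuous
variables get Shapiro–Wilk on each group at α = 0.05 (capped at 5,000
observations), Student's t if both pass, Mann–Whitney U otherwise.  No
multiplicity correction by default (mirroring common practice in this
literature); Benjamini–Hochberg is available via `bh_correction=True`.

The benefit model is a main-effects logistic regression of high/low
group membership on six default predictors (urine output, creatinine,
lactate, WBC, glucose, respiratory rate; configurable), with Wald 95%
CIs.  The nomogram follows the standard regression-nomogram
construction: `points_i(x) = 100·|β_i|·|x − x_ref,i| / max_j(|β_j|·range_j)`
with the reference at the range endpoint minimizing `β_i·x`, so points
are non-negative, the largest axis spans exactly 0–100, and total points
map back through the logistic function — making the reconstruction
algebraically exact (round-trip error 0 up to floating point; the
contract allows 0.01 to cover future breakpoint-table interpolation).

`power_two_proportions` uses the classical normal approximation (pooled
SE under the null, unpooled under the alternative); at rates 0.393 vs
0.323 with 458 per arm and α = 0.05 it computes ≈ 0.60, and a
t-test-on-binary variant agrees to two decimals.  Published claims of
>99.9% power for these inputs do not recompute under any standard
formula; the package reports the computed value.

## Problem sizes and determinism

Default analyses run at the study scale (8,289 stays; ~400–450 matched
pairs).  Validation suites use: 1,000 random instances of ≤30 patients
for brute-force qini equivalence; five seeds of n = 6,000 / 8% treated
for matching balance; five seeds of n = 8,000 randomized 50/50 (~4,000
per arm) for effect recovery (held-out Spearman ≥ 0.4 in every seed
under the default effect structure); 100,000 simulated trials for the
power oracle.  Every stochastic step takes an explicit seed; repeated
runs are bit-identical.

## Known limitations

* The class-transformation identity needs `P(T=1|X) = 1/2`; after
  caliper matching this holds only approximately on new data.
* Greedy matching is order-dependent by construction (optimal matching
  is out of scope), and the caliper means not every treated patient is
  matched.
* The generator's independence of covariate marginals understates the
  collinearity of real ICU labs; SHAP attributions on real data would be
  correspondingly less crisp.
* No survival-time modeling: the endpoint is a fixed 28-day binary flag.
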