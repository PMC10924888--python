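# rrtuplift

Who benefits from renal replacement therapy (RRT) in sepsis-associated
acute kidney injury (S-AKI)?  Average treatment effects from observational
ICU cohorts answer the wrong question at the bedside: clinicians start RRT
patient by patient, and the benefit is heterogeneous.  `rrtuplift`
implements an individual-treatment-effect (uplift) analysis pipeline for
such cohorts — one row per ICU stay, a binary treatment flag (RRT) and a
binary 28-day death flag — together with a synthetic-cohort generator that
carries exact ground-truth potential outcomes, so every stage of the
pipeline can be validated without access to a credentialed EHR database.

It is written for biostatisticians and critical-care data scientists who
want a tested, reusable implementation of this analysis rather than a
one-off notebook.

## The method

**Class transformation.** Each patient with covariates X, treatment T and
28-day survival S gets the transformed label

    Z = 1  if (T = 1 and S = 1) or (T = 0 and S = 0),    Z = 0 otherwise.

When P(T = 1 | X) = 1/2 — arranged by 1:1 propensity matching — a
calibrated classifier for Z satisfies

    uplift(X) = 2·P(Z = 1 | X) − 1
              = P(S = 1 | T = 1, X) − P(S = 1 | T = 0, X),

the individual benefit of treatment on the survival-probability scale.  A
single gradient-boosted classifier (penalized logistic regression as an
alternative) therefore estimates the treatment effect directly.

**Adjusted qini evaluation.** A ranker is scored by how well it
concentrates benefit: for a fraction φ, take the top-φ patients of each
arm by score and compute

    Q(φ) = n_t1(φ)/N_t − n_c1(φ)·n_t(φ) / (N_t·n_c(φ)),

where n_t(φ), n_c(φ) are the selected counts and n_t1, n_c1 the observed
survivors among them.  Q(1) is the overall survival-rate difference; the
AUUC is the area between the qini curve and the straight chord from
(0, 0) to (1, Q(1)).  AUUC > 0 means the ranker targets treatment better
than random selection.  Clinical severity scores (SOFA, KDIGO stage) can
be plugged in as comparator rankers.

**Around the model**: KDIGO AKI staging and study inclusion filters with
an attrition log, propensity-score matching (logistic propensity, greedy
1:1 nearest-neighbor on the logit scale, caliper 0.2 SD by default) with
standardized-mean-difference balance reporting, benefit-group profiling
(test selection between Student's t, Mann–Whitney and Yates chi-square),
a logistic benefit model with odds-ratio table, and a regression nomogram
mapping the six benefit predictors to a 0–100 point scale.

## Worked example

```python
import pandas as pd
from rrtuplift import (SimConfig, generate_cohort, apply_cohort_filters,
                       match_cohort, SplitSpec, split_development_validation,
                       ClassTransformationUplift, qini_curve,
                       rank_by_clinical_score)
from rrtuplift.matching import DEFAULT_PSM_COVARIATES

# observational cohort at study scale: 8,289 stays, ~7% treated, confounded
cohort, attrition = apply_cohort_filters(generate_cohort(SimConfig(seed=42)))
print(attrition.to_text())

mr = match_cohort(cohort)
print(f"matched pairs: {len(mr.pairs)}  "
      f"(mean |SMD| {mr.balance.smd_before.mean():.3f} -> {mr.balance.smd_after.mean():.3f})")

matched = cohort.set_index("id").loc[mr.matched_ids].reset_index()
n_dev = round(0.7 * len(matched))
dev, val = split_development_validation(
    matched, SplitSpec(n_dev, len(matched) - n_dev, seed=42))

features = [f for f in DEFAULT_PSM_COVARIATES if f in matched.columns]
results = ClassTransformationUplift(dev, features).fit(seed=42)
print(results.summary())

surv = 1 - val["died_28d"]
for label, scores in [("class transformation", results.uplift_score(val)),
                      ("SOFA", rank_by_clinical_score(val, "sofa")),
                      ("KDIGO stage", rank_by_clinical_score(val, "kdigo_stage"))]:
    c = qini_curve(scores, val["treated"], surv, label=label, ids=val["id"])
    print(f"AUUC {label:<22}{c.auuc:+.4f}")
```

Output:

```
input records: 8289
  - sepsis-3 criteria met: removed 0, remaining 8289
  - AKI: highest KDIGO stage >= 1: removed 1794, remaining 6495
  - first ICU admission: removed 544, remaining 5951
  - age >= 18: removed 0, remaining 5951
  - no end-stage renal disease: removed 174, remaining 5777
  - potassium <= 6.5 mmol/l: removed 48, remaining 5729
final cohort: 5729
matched pairs: 413  (mean |SMD| 0.115 -> 0.055)
Class-transformation uplift model
================================================
learner:        gbt
features:       21
training arms:  treated=289, control=289
seed:           42
train P(Z=1|X): mean=0.510
train uplift:   mean=+0.020, IQR=[-0.509, +0.547]
AUUC class transformation  -0.0012
AUUC SOFA                  +0.0109
AUUC KDIGO stage           +0.0028
```

Matching removes the confounded imbalance (mean |SMD| 0.115 → 0.055,
every severity covariate below the 0.1 balance convention) and the mean
estimated uplift (+0.02 on the survival scale) sits near the generator's
average benefit.  Note what the AUUC row honestly shows: with only ~250
validation patients, a single-split AUUC is dominated by sampling noise —
its sign flips from seed to seed for every ranker.  Judging the method
itself needs ground truth, which the synthetic cohorts provide:

```python
from scipy.stats import spearmanr
from rrtuplift import true_uplift

cfg = SimConfig(n_patients=8000, treat_fraction_target=0.5,
                confounding_strength=0.0, seed=42)   # randomized trial
rct = generate_cohort(cfg)
dev, val = split_development_validation(rct, SplitSpec(5600, 2400, seed=42))
res = ClassTransformationUplift(dev, features).fit(seed=42)
scores = res.uplift_score(val)
print(f"held-out Spearman(uplift score, true benefit): "
      f"{spearmanr(scores, true_uplift(val)).statistic:.3f}")
```

```
held-out Spearman(uplift score, true benefit): 0.456
```

On a randomized cohort with ~4,000 patients per arm the model's uplift
scores correlate substantially with each patient's true (generator-known)
benefit, and its qini curve sits above the random chord (AUUC +0.0069 on
this split).

## Cohort table schema

A cohort is a flat CSV, one row per ICU stay.  Required columns: `id`,
`treated`, `died_28d`, `age`, `sofa`, `kdigo_stage`,
`first_icu_admission`, `esrd`, `potassium`.  The generator also writes
`qsofa`, `kdigo_stage_highest`, first-24h vitals (`map`, `temperature`,
`heart_rate`, `resp_rate`, `spo2`), labs in fixed units (`urine_output`
ml/24h, `fluid_input` ml/24h, `lactate` mmol/l, `creatinine` mg/dl, `wbc`
10⁹/l, `bun` mg/dl, `glucose` mg/dl, `sodium`, `chloride`, `potassium`
mmol/l, `ph`, `platelet` 10⁹/l), a `sepsis` flag, and — synthetic cohorts
only — the potential-outcome probabilities `p_death_control`,
`p_death_treated` plus the true assignment propensity.  `write_cohort`
emits a `.meta.json` sidecar with the schema version and (optionally) the
generating configuration; `read_cohort` validates the required columns.

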