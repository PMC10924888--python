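"""Class-transformation uplift modeling.

The individual treatment effect (ITE) of a binary treatment on a binary
outcome is estimated through a single classifier.  Each subject gets a
transformed label

    Z = 1  if treated and survived 28 days, or untreated and died,
    Z = 0  otherwise,

and with equal arm sizes (or, more generally, P(treated | X) = 1/2) a
calibrated classifier satisfies

    2 P(Z = 1 | X) - 1 = P(survive | treated, X) - P(survive | control, X),

so ``uplift = 2 P(Z=1|X) - 1`` is the treatment benefit on the survival
scale.  The model object follows the statsmodels convention: construct
from a cohort DataFrame, ``fit()`` returns a results object carrying the
fitted estimator, scores, and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "transform_labels",
    "expected_z_probability",
    "uplift_from_z_probability",
    "SplitSpec",
    "split_development_validation",
    "split_benefit_groups",
    "ClassTransformationUplift",
    "ClassTransformationUpliftResults",
]

_PROB_CLIP = 1e-6  # avoid spurious +-1 uplift saturation from overfit trees


def transform_labels(treated, died_28d):
    """Transformed class label Z.

    Truth table: (treated, survived) -> 1; (control, died) -> 1;
    (treated, died) -> 0; (control, survived) -> 0.  Vectorized; inputs
    must be 0/1 or boolean with no missing values.
    """
    t = np.asarray(treated)
    d = np.asarray(died_28d)
    if np.any(pd.isna(t)) or np.any(pd.isna(d)):
        raise ValueError("treated/died_28d contain missing values")
    t = t.astype(int)
    d = d.astype(int)
    if not (np.isin(t, (0, 1)).all() and np.isin(d, (0, 1)).all()):
        raise ValueError("treated and died_28d must be binary flags")
    survived = 1 - d
    z = t * survived + (1 - t) * d
    return z if z.ndim else int(z)


def expected_z_probability(p_death_control, p_death_treated, treat_prob: float = 0.5):
    """Analytic P(Z = 1 | X) given the potential-outcome death
    probabilities and the treatment probability:

    P(Z=1|X) = P(T=1) P(survive|T=1,X) + P(T=0) P(die|T=0,X).
    """
    pc = np.asarray(p_death_control, dtype=float)
    pt = np.asarray(p_death_treated, dtype=float)
    return treat_prob * (1.0 - pt) + (1.0 - treat_prob) * pc


def uplift_from_z_probability(p_z):
    """Uplift score = 2 P(Z=1|X) - 1, in [-1, 1]."""
    return 2.0 * np.asarray(p_z, dtype=float) - 1.0


# --------------------------------------------------------------------------
# cohort splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Development/validation split sizes (must sum to the cohort size);
    stratified by treatment arm by default."""

    n_development: int
    n_validation: int
    stratify_treatment: bool = True
    seed: int = 0


def split_development_validation(
    table: pd.DataFrame, spec: SplitSpec, treatment: str = "treated"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random split into development and validation cohorts, preserving
    the treatment proportion in both when stratified.  Deterministic given
    ``spec.seed``."""
    n = len(table)
    if spec.n_development + spec.n_validation != n:
        raise ValueError(
            f"split sizes {spec.n_development}+{spec.n_validation} do not sum to cohort size {n}"
        )
    if spec.n_development <= 0 or spec.n_validation <= 0:
        raise ValueError("both split sizes must be positive")

    rng = np.random.default_rng(spec.seed)
    if not spec.stratify_treatment:
        perm = rng.permutation(n)
        dev_idx = table.index[perm[: spec.n_development]]
    else:
        dev_parts = []
        remaining = spec.n_development
        groups = [(g, sub) for g, sub in table.groupby(treatment)]
        for k, (_, sub) in enumerate(groups):
            # proportional allocation; last stratum absorbs rounding
            take = remaining if k == len(groups) - 1 else round(spec.n_development * len(sub) / n)
            if not 0 <= take <= len(sub):
                raise ValueError("stratified split infeasible with these arm sizes")
            perm = rng.permutation(len(sub))
            dev_parts.append(sub.index[perm[:take]])
            remaining -= take
        dev_idx = dev_parts[0].append(dev_parts[1:]) if len(dev_parts) > 1 else dev_parts[0]

    dev = table.loc[table.index.isin(dev_idx)]
    val = table.loc[~table.index.isin(dev_idx)]
    return dev.copy(), val.copy()


def split_benefit_groups(scores: pd.Series | list[tuple]) -> pd.Series:
    """Median split of uplift scores into 'high' and 'low' benefit groups.

    Accepts a Series (id -> score) or a list of (id, score).  Groups
    differ in size by at most one (odd n puts the extra record in 'high');
    ties broken by ascending id for determinism.
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(dict(scores))
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    order = sorted(scores.index, key=lambda i: (-scores[i], i))
    n_high = (n + 1) // 2
    labels = pd.Series("low", index=scores.index, name="benefit_group")
    labels.loc[order[:n_high]] = "high"
    return labels


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class ClassTransformationUplift:
    """Class-transformation uplift model on a cohort table.

    Parameters
    ----------
    data : cohort DataFrame with ``treatment`` and ``outcome`` columns.
    features : predictor column names.
    treatment, outcome : binary flag columns (outcome = death, so the
        model internally works with survival = 1 - outcome).
    learner : ``"gbt"`` (gradient-boosted trees, default — supports exact
        additive TreeSHAP attributions) or ``"logistic"`` (standardized
        penalized logistic regression).
    learner_params : overrides for the underlying estimator.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features: list[str],
        treatment: str = "treated",
        outcome: str = "died_28d",
        learner: str = "gbt",
        learner_params: dict | None = None,
    ):
        missing = [c for c in [*features, treatment, outcome] if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns: {missing}")
        self.data = data
        self.features = list(features)
        self.treatment = treatment
        self.outcome = outcome
        self.learner = learner
        self.learner_params = dict(learner_params or {})

        t = data[treatment].astype(int)
        self.n_treated = int(t.sum())
        self.n_control = int((1 - t).sum())
        if self.n_treated == 0 or self.n_control == 0:
            raise ValueError("both treatment arms must be present to fit an uplift model")

    def _make_estimator(self, seed: int):
        if self.learner == "gbt":
            from xgboost import XGBClassifier

            params = dict(
                n_estimators=300,
                max_depth=3,
                learning_rate=0.05,
                subsample=0.8,
                colsample_bytree=0.8,
                reg_lambda=1.0,
                tree_method="hist",
                n_jobs=1,
                random_state=seed,
                eval_metric="logloss",
            )
            params.update(self.learner_params)
            return XGBClassifier(**params)
        if self.learner == "logistic":
            from sklearn.linear_model import LogisticRegression
            from sklearn.pipeline import Pipeline
            from sklearn.preprocessing import StandardScaler

            params = dict(C=1.0, max_iter=2000)
            params.update(self.learner_params)
            return Pipeline(
                [("scale", StandardScaler()), ("clf", LogisticRegression(**params))]
            )
        raise ValueError(f"unknown learner {self.learner!r}")

    def fit(self, seed: int = 0) -> "ClassTransformationUpliftResults":
        """Fit P(Z=1|X) on the cohort.  Deterministic given ``seed``."""
        z = transform_labels(self.data[self.treatment], self.data[self.outcome])
        if len(np.unique(z)) < 2:
            raise ValueError("transformed label Z is single-class; cannot fit a classifier")

        unequal = self.n_treated != self.n_control
        if unequal:
            warnings.warn(
                f"treatment arms are unequal ({self.n_treated} vs {self.n_control}); "
                "2*P(Z=1|X)-1 is only an unbiased uplift when P(treated|X)=1/2 "
                "(e.g. after 1:1 matching)",
                UserWarning,
                stacklevel=2,
            )

        X = self.data[self.features].astype(float)
        medians = X.median()  # development-cohort medians for imputation
        X = X.fillna(medians)

        est = self._make_estimator(seed)
        est.fit(X.to_numpy(), np.asarray(z))

        return ClassTransformationUpliftResults(
            model=self,
            estimator=est,
            seed=seed,
            feature_medians=medians,
            unequal_arms_warning=unequal,
        )


class ClassTransformationUpliftResults:
    """Fitted class-transformation uplift model."""

    def __init__(self, model, estimator, seed, feature_medians, unequal_arms_warning):
        self.model = model
        self.estimator = estimator
        self.seed = seed
        self.feature_medians = feature_medians
        self.unequal_arms_warning = unequal_arms_warning

    # -- prediction ------------------------------------------------------
    def _matrix(self, data: pd.DataFrame) -> np.ndarray:
        X = data[self.model.features].astype(float)
        return X.fillna(self.feature_medians).to_numpy()

    def predict_z(self, data: pd.DataFrame) -> np.ndarray:
        """P(Z = 1 | X), clipped away from {0, 1}."""
        p = self.estimator.predict_proba(self._matrix(data))[:, 1]
        return np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP)

    def uplift_score(self, data: pd.DataFrame) -> np.ndarray:
        """Estimated ITE on the survival scale: 2 P(Z=1|X) - 1."""
        return uplift_from_z_probability(self.predict_z(data))

    def score_table(self, data: pd.DataFrame, id_col: str = "id") -> pd.DataFrame:
        """Per-record scores: id, p_z, uplift_score, benefit_group."""
        p_z = self.predict_z(data)
        out = pd.DataFrame(
            {
                id_col: data[id_col].to_numpy(),
                "p_z": p_z,
                "uplift_score": uplift_from_z_probability(p_z),
            }
        )
        groups = split_benefit_groups(pd.Series(out["uplift_score"].to_numpy(), index=out[id_col]))
        out["benefit_group"] = groups.loc[out[id_col]].to_numpy()
        return out

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Class-transformation uplift model",
            "=" * 48,
            f"learner:        {m.learner}",
            f"features:       {len(m.features)}",
            f"training arms:  treated={m.n_treated}, control={m.n_control}"
            + ("  (WARNING: unequal)" if self.unequal_arms_warning else ""),
            f"seed:           {self.seed}",
        ]
        p_train = self.predict_z(m.data)
        u = uplift_from_z_probability(p_train)
        lines += [
            f"train P(Z=1|X): mean={p_train.mean():.3f}",
            f"train uplift:   mean={u.mean():+.3f}, IQR=[{np.quantile(u, 0.25):+.3f}, "
            f"{np.quantile(u, 0.75):+.3f}]",
        ]
        return "\n".join(lines)
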