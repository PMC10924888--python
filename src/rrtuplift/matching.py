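"""Propensity-score matching: logistic propensity model, 1:1 greedy
nearest-neighbor matching on the logit scale, and standardized mean
differences (SMD) for balance assessment.

The matching protocol is fully deterministic: treated subjects are
processed in descending propensity order and each takes the unmatched
control with the smallest absolute logit-propensity distance (ties to the
lower id), without replacement.  An optional caliper (default 0.2 SD of
the logit propensity, the usual convention) discards pairs whose distance
exceeds it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MatchResult",
    "fit_propensity",
    "greedy_match",
    "standardized_mean_difference",
    "match_cohort",
    "DEFAULT_PSM_COVARIATES",
]

#: Baseline covariates matched on by default (all schema variables that
#: are plausibly pre-treatment).
DEFAULT_PSM_COVARIATES = [
    "age", "sofa", "qsofa", "kdigo_stage", "urine_output", "fluid_input",
    "map", "temperature", "heart_rate", "resp_rate", "spo2", "lactate",
    "creatinine", "wbc", "bun", "glucose", "sodium", "chloride",
    "potassium", "ph", "platelet",
]

_EPS = 1e-9


@dataclass
class MatchResult:
    """Outcome of one 1:1 matching run."""

    pairs: list[tuple[int, int]]                 # (treated id, control id)
    propensity: pd.Series                        # id -> P(treated | X)
    caliper_used: float | None                   # absolute logit-scale caliper
    n_unmatched_treated: int
    balance: pd.DataFrame                        # covariate, smd_before, smd_after

    @property
    def matched_ids(self) -> list[int]:
        return [i for pair in self.pairs for i in pair]

    def balance_to_csv(self, path) -> None:
        self.balance.to_csv(path, index=False)

    def pairs_to_csv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["treated_id", "control_id"]).to_csv(path, index=False)


def fit_propensity(
    table: pd.DataFrame,
    covariates: list[str],
    treatment: str = "treated",
    id_col: str = "id",
) -> pd.Series:
    """Main-effects logistic regression of treatment on covariates.

    Returns a Series mapping id -> estimated propensity in (0, 1).
    Constant covariates are dropped with a warning; a covariate that
    perfectly separates the arms raises with its name.
    """
    y = table[treatment].astype(int)
    if y.nunique() < 2 or y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 subjects in each treatment arm")

    X = table[covariates].astype(float)
    const = [c for c in covariates if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant covariates from propensity model: {const}", stacklevel=2)
        X = X.drop(columns=const)

    for c in X.columns:  # cheap separation screen with an informative name
        t_vals, c_vals = X.loc[y == 1, c], X.loc[y == 0, c]
        if t_vals.min() > c_vals.max() or c_vals.min() > t_vals.max():
            raise ValueError(f"perfect separation on covariate {c!r}")

    model = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy()))
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise ValueError(f"propensity model failed to fit: {exc}") from exc

    ps = np.clip(res.predict(), _EPS, 1 - _EPS)
    return pd.Series(ps, index=table[id_col].to_numpy(), name="propensity")


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def greedy_match(
    propensity: pd.Series,
    treated_ids: np.ndarray | list,
    control_ids: np.ndarray | list,
    caliper: float | None = None,
) -> list[tuple[int, int]]:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Treated subjects are processed in descending propensity (ties by
    ascending id); each is paired with the unmatched control minimizing
    the absolute difference in logit propensity, skipped if that distance
    exceeds ``caliper`` (an absolute logit-scale distance; None disables).
    """
    treated_ids = np.asarray(treated_ids)
    control_ids = np.asarray(control_ids)
    if len(control_ids) == 0:
        raise ValueError("control pool is empty")

    lp = pd.Series(_logit(propensity.to_numpy()), index=propensity.index)

    t_order = sorted(treated_ids, key=lambda i: (-propensity[i], i))
    c_arr = np.array(sorted(control_ids))  # ascending id = tie-break order
    c_logits = lp[c_arr].to_numpy()
    available = np.ones(len(c_arr), dtype=bool)

    pairs: list[tuple[int, int]] = []
    for t in t_order:
        if not available.any():
            break
        d = np.abs(c_logits - lp[t])
        d[~available] = np.inf
        best = int(np.argmin(d))  # argmin takes the first = lowest id on ties
        if caliper is None or d[best] <= caliper:
            available[best] = False
            pairs.append((t, c_arr[best]))
    return pairs


def standardized_mean_difference(values_t, values_c, kind: str = "continuous") -> float:
    """Absolute standardized mean difference between two samples.

    continuous: |m_t - m_c| / sqrt((s_t^2 + s_c^2) / 2), sample SDs;
    binary:     |p_t - p_c| / sqrt((p_t(1-p_t) + p_c(1-p_c)) / 2).

    A zero pooled variance yields 0 when the means agree and is an error
    otherwise (the difference would be infinite).
    """
    a = np.asarray(values_t, dtype=float)
    b = np.asarray(values_c, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both arms need at least one observation")

    if kind == "binary":
        pt, pc = a.mean(), b.mean()
        denom2 = (pt * (1 - pt) + pc * (1 - pc)) / 2
        diff = pt - pc
    elif kind == "continuous":
        denom2 = (a.var(ddof=1) + b.var(ddof=1)) / 2 if (len(a) > 1 or len(b) > 1) else 0.0
        if len(a) == 1:
            denom2 = b.var(ddof=1) / 2 if len(b) > 1 else 0.0
        elif len(b) == 1:
            denom2 = a.var(ddof=1) / 2
        diff = a.mean() - b.mean()
    else:
        raise ValueError("kind must be 'continuous' or 'binary'")

    if denom2 <= 0:
        if abs(diff) < 1e-12:
            return 0.0
        raise ValueError("zero pooled variance with unequal means: SMD undefined")
    return abs(diff) / np.sqrt(denom2)


def _smd_auto(df: pd.DataFrame, mask_t: pd.Series, mask_c: pd.Series, col: str) -> float:
    vals = df[col]
    kind = "binary" if set(pd.unique(vals.dropna())) <= {0, 1, True, False} else "continuous"
    return standardized_mean_difference(vals[mask_t], vals[mask_c], kind)


def match_cohort(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    treatment: str = "treated",
    id_col: str = "id",
    caliper: float | str | None = "auto",
) -> MatchResult:
    """Full PSM workflow: fit propensities, greedy-match 1:1, and compute
    per-covariate SMD before and after matching.

    ``caliper="auto"`` uses 0.2 x SD of the logit propensity; a float is
    an absolute logit-scale distance; None disables the caliper.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_PSM_COVARIATES if c in table.columns]

    ps = fit_propensity(table, covariates, treatment=treatment, id_col=id_col)
    treated_ids = table.loc[table[treatment] == 1, id_col].to_numpy()
    control_ids = table.loc[table[treatment] == 0, id_col].to_numpy()

    if caliper == "auto":
        caliper_val: float | None = 0.2 * float(np.std(_logit(ps.to_numpy()), ddof=1))
    else:
        caliper_val = caliper  # type: ignore[assignment]

    pairs = greedy_match(ps, treated_ids, control_ids, caliper=caliper_val)

    idx = table.set_index(id_col)
    matched_t = idx.loc[[p[0] for p in pairs]]
    matched_c = idx.loc[[p[1] for p in pairs]]

    rows = []
    mask_t, mask_c = table[treatment] == 1, table[treatment] == 0
    for c in covariates:
        before = _smd_auto(table, mask_t, mask_c, c)
        vals = table[c]
        kind = "binary" if set(pd.unique(vals.dropna())) <= {0, 1, True, False} else "continuous"
        after = standardized_mean_difference(matched_t[c], matched_c[c], kind)
        rows.append({"covariate": c, "smd_before": before, "smd_after": after})

    return MatchResult(
        pairs=pairs,
        propensity=ps,
        caliper_used=caliper_val,
        n_unmatched_treated=len(treated_ids) - len(pairs),
        balance=pd.DataFrame(rows),
    )
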