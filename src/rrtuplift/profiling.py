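"""Characterization of high- vs low-benefit patients.

Covers the classical-statistics layer around the uplift model: per-variable
group comparisons with an explicit test-selection rule, the multivariable
logistic model of benefit-group membership (odds-ratio table), a regression
nomogram derived from that model, the two-proportion (Yates chi-square)
test, and two-proportion power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "compare_groups",
    "BenefitLogistic",
    "BenefitLogisticResults",
    "fit_benefit_logistic",
    "Nomogram",
    "build_nomogram",
    "two_proportion_test",
    "power_two_proportions",
]

#: The six benefit-model predictors used by default.
DEFAULT_BENEFIT_VARIABLES = ["urine_output", "creatinine", "lactate", "wbc", "glucose", "resp_rate"]


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def _is_binary(x: pd.Series) -> bool:
    return set(pd.unique(x.dropna())) <= {0, 1, True, False}


def compare_groups(
    table: pd.DataFrame,
    labels: pd.Series,
    variables: list[str],
    normality_alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-variable two-group comparison with an explicit selection rule.

    Binary variables: chi-square on the 2x2 table (Yates-corrected).
    Continuous: Shapiro-Wilk on each group at ``normality_alpha``; both
    normal -> Student's t-test, otherwise Mann-Whitney U.  Constant
    variables are flagged with p = NaN.  Benjamini-Hochberg adjusted
    p-values are added only when ``bh_correction`` (default off).
    """
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    g1 = table.loc[np.asarray(labels) == groups[0]]
    g2 = table.loc[np.asarray(labels) == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be nonempty")

    rows = []
    for v in variables:
        a, b = g1[v].dropna(), g2[v].dropna()
        row = {"variable": v, "n_1": len(a), "n_2": len(b)}
        if a.nunique() <= 1 and b.nunique() <= 1 and (len(a) == 0 or len(b) == 0 or a.iloc[0] == b.iloc[0]):
            row.update(test="constant", statistic=np.nan, p=np.nan, flag="constant variable")
        elif _is_binary(table[v]):
            tab = np.array([[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float)
            if (tab.sum(axis=0) == 0).any():
                row.update(test="chi-square", statistic=np.nan, p=np.nan, flag="degenerate 2x2")
            else:
                chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
                row.update(
                    test="chi-square", statistic=chi2, p=p,
                    summary_1=f"{int(a.sum())} ({a.mean():.1%})",
                    summary_2=f"{int(b.sum())} ({b.mean():.1%})",
                )
        else:
            # Shapiro-Wilk is capped at 5000 obs (scipy limit is soft but
            # power there is excessive anyway)
            wa = stats.shapiro(a.sample(min(len(a), 5000), random_state=0)) if a.nunique() > 1 else None
            wb = stats.shapiro(b.sample(min(len(b), 5000), random_state=0)) if b.nunique() > 1 else None
            normal = (
                wa is not None and wb is not None
                and wa.pvalue > normality_alpha and wb.pvalue > normality_alpha
            )
            if normal:
                s, p = stats.ttest_ind(a, b, equal_var=True)
                row.update(test="t", statistic=s, p=p)
            else:
                s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                row.update(test="mann-whitney", statistic=s, p=p)
            row.update(
                summary_1=f"{a.mean():.2f} [{a.median():.2f}]",
                summary_2=f"{b.mean():.2f} [{b.median():.2f}]",
            )
        rows.append(row)

    out = pd.DataFrame(rows)
    if bh_correction and out["p"].notna().any():
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        out.loc[mask, "p_bh"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# benefit logistic model (statsmodels-style model/results pair)
# --------------------------------------------------------------------------

class BenefitLogistic:
    """Main-effects logistic regression of benefit-group membership
    (1 = high benefit) on a set of clinical variables."""

    def __init__(self, data: pd.DataFrame, labels, variables: list[str] | None = None):
        self.variables = list(variables or DEFAULT_BENEFIT_VARIABLES)
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise ValueError(f"data is missing variables: {missing}")
        y = np.asarray(labels)
        if y.dtype.kind in "OU":  # 'high'/'low' labels
            y = (y == "high").astype(int)
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("labels must contain both groups")
        if len(data) <= len(self.variables) + 1:
            raise ValueError("fewer rows than model parameters")
        self.data = data
        self.y = y

    def fit(self) -> "BenefitLogisticResults":
        X = sm.add_constant(self.data[self.variables].astype(float))
        try:
            res = sm.Logit(self.y, X).fit(disp=0, maxiter=500)
        except Exception as exc:
            raise ValueError(f"benefit logistic model failed (separation?): {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise ValueError("benefit logistic model did not converge (separation?)")
        return BenefitLogisticResults(self, res)


class BenefitLogisticResults:
    """Fitted benefit model: OR table, summary, and nomogram factory."""

    def __init__(self, model: BenefitLogistic, smres):
        self.model = model
        self._res = smres
        self.params = smres.params  # includes 'const'

    def or_table(self) -> pd.DataFrame:
        """Odds ratios with Wald 95% CIs and p-values, one row per variable."""
        conf = self._res.conf_int()
        rows = []
        for v in self.model.variables:
            rows.append(
                {
                    "variable": v,
                    "OR": float(np.exp(self.params[v])),
                    "CI_low": float(np.exp(conf.loc[v, 0])),
                    "CI_high": float(np.exp(conf.loc[v, 1])),
                    "p": float(self._res.pvalues[v]),
                }
            )
        return pd.DataFrame(rows)

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(data[self.model.variables].astype(float), has_constant="add")
        return np.asarray(self._res.predict(X))

    def build_nomogram(self, variable_ranges: dict[str, tuple[float, float]] | None = None) -> "Nomogram":
        return build_nomogram(self, variable_ranges)

    def summary(self) -> str:
        tab = self.or_table()
        lines = ["Benefit logistic model (high vs low benefit)", "=" * 48]
        lines.append(f"{'variable':<14}{'OR':>8}{'95% CI':>18}{'p':>10}")
        for _, r in tab.iterrows():
            lines.append(
                f"{r['variable']:<14}{r['OR']:>8.2f}"
                f"{f'{r.CI_low:.2f}-{r.CI_high:.2f}':>18}{r['p']:>10.3g}"
            )
        return "\n".join(lines)


def fit_benefit_logistic(
    table: pd.DataFrame, labels, variables: list[str] | None = None
) -> pd.DataFrame:
    """Convenience wrapper returning just the OR table."""
    return BenefitLogistic(table, labels, variables).fit().or_table()


# --------------------------------------------------------------------------
# nomogram
# --------------------------------------------------------------------------

@dataclass
class Nomogram:
    """Regression nomogram: each variable maps linearly to a 0-100 point
    axis; the total-points axis maps back to probability through the
    underlying logistic model.

    points_i(x) = 100 * |beta_i| * (x - x_ref_i) / max_j(|beta_j| * range_j),
    with x_ref_i the range endpoint minimizing beta_i * x, so points are
    non-negative over the declared range and probability is strictly
    increasing in total points.
    """

    variables: list[str]
    coefs: dict[str, float]          # per-variable beta
    intercept: float
    ranges: dict[str, tuple[float, float]]
    ref_points: dict[str, float]     # x_ref per variable
    scale: float                     # log-odds per nomogram point

    def points(self, variable: str, value) -> np.ndarray | float:
        lo, hi = self.ranges[variable]
        x = np.clip(np.asarray(value, dtype=float), lo, hi)
        beta = self.coefs[variable]
        pts = abs(beta) * (x - self.ref_points[variable]) / self.scale
        pts = np.abs(pts)  # sign handled by x_ref; abs guards -0.0
        return pts if pts.ndim else float(pts)

    def total_points(self, profile: dict[str, float] | pd.Series | pd.DataFrame):
        if isinstance(profile, pd.DataFrame):
            return sum(self.points(v, profile[v].to_numpy()) for v in self.variables)
        return float(sum(self.points(v, profile[v]) for v in self.variables))

    def probability_from_points(self, total_points):
        """Probability of high benefit implied by a total-points score."""
        base = self.intercept + sum(
            self.coefs[v] * self.ref_points[v] for v in self.variables
        )
        eta = base + self.scale * np.asarray(total_points, dtype=float)
        p = 1.0 / (1.0 + np.exp(-eta))
        return p if p.ndim else float(p)

    def predict_proba(self, profile) -> np.ndarray | float:
        return self.probability_from_points(self.total_points(profile))

    def axis_table(self, variable: str, n: int = 11) -> pd.DataFrame:
        lo, hi = self.ranges[variable]
        grid = np.linspace(lo, hi, n)
        return pd.DataFrame({"value": grid, "points": self.points(variable, grid)})

    def total_points_table(self, n: int = 21) -> pd.DataFrame:
        tmax = sum(self.points(v, self.ranges[v][0 if self.coefs[v] < 0 else 1]) for v in self.variables)
        grid = np.linspace(0.0, float(tmax), n)
        return pd.DataFrame({"total_points": grid, "probability": self.probability_from_points(grid)})

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.variables,
                "axes": {v: self.axis_table(v).to_dict("list") for v in self.variables},
                "total_points_to_probability": self.total_points_table().to_dict("list"),
                "coefficients": {**self.coefs, "intercept": self.intercept},
                "ranges": {v: list(r) for v, r in self.ranges.items()},
            },
            indent=2,
        )


def build_nomogram(
    fit: BenefitLogisticResults,
    variable_ranges: dict[str, tuple[float, float]] | None = None,
) -> Nomogram:
    """Construct the nomogram from a fitted benefit model.

    ``variable_ranges`` default to the observed min/max of each variable
    in the training data; ranges must be finite and non-degenerate.
    """
    variables = fit.model.variables
    coefs = {v: float(fit.params[v]) for v in variables}
    if all(abs(b) < 1e-12 for b in coefs.values()):
        raise ValueError("all coefficients are zero; nomogram undefined")

    if variable_ranges is None:
        variable_ranges = {
            v: (float(fit.model.data[v].min()), float(fit.model.data[v].max())) for v in variables
        }
    for v, (lo, hi) in variable_ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
            raise ValueError(f"invalid range for {v!r}: ({lo}, {hi})")

    # 100 points = the single largest |beta| * range span
    k = max(abs(coefs[v]) * (variable_ranges[v][1] - variable_ranges[v][0]) for v in variables)
    scale = k / 100.0  # log-odds per point

    ref_points = {}
    for v in variables:
        lo, hi = variable_ranges[v]
        # reference = endpoint minimizing beta * x (zero points there)
        ref_points[v] = lo if coefs[v] >= 0 else hi

    return Nomogram(
        variables=list(variables),
        coefs=coefs,
        intercept=float(fit.params["const"]),
        ranges=dict(variable_ranges),
        ref_points=ref_points,
        scale=scale,
    )


# --------------------------------------------------------------------------
# two-proportion inference
# --------------------------------------------------------------------------

def two_proportion_test(events_1: int, n_1: int, events_2: int, n_2: int) -> tuple[float, float]:
    """Yates-corrected chi-square test of two proportions (two-sided).

    Returns (statistic, p).  Symmetric in group order.
    """
    if not (0 <= events_1 <= n_1 and 0 <= events_2 <= n_2):
        raise ValueError("events must lie in [0, n]")
    tab = np.array([[events_1, n_1 - events_1], [events_2, n_2 - events_2]], dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (zero margin)")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
    return float(chi2), float(p)


def power_two_proportions(
    p1: float, p2: float, n: int, alpha: float = 0.05, method: str = "normal"
) -> float:
    """Two-sided power to detect a difference of two proportions with n
    subjects per group.

    method='normal': classical normal approximation (pooled null SE,
    unpooled alternative SE) for the two-sample z-test of proportions.
    method='ttest': power of a two-sample t-test applied to the binary
    outcomes (Cohen's d from the pooled binomial SD), for comparability
    with sample-size calculations phrased as t-tests.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2 per group")

    if method == "normal":
        pbar = (p1 + p2) / 2
        se0 = np.sqrt(2 * pbar * (1 - pbar) / n)
        se1 = np.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
        za = stats.norm.ppf(1 - alpha / 2)
        d = abs(p1 - p2)
        return float(
            stats.norm.cdf((d - za * se0) / se1) + stats.norm.cdf((-d - za * se0) / se1)
        )
    if method == "ttest":
        from statsmodels.stats.power import TTestIndPower

        sd = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
        d = abs(p1 - p2) / sd
        return float(TTestIndPower().power(effect_size=d, nobs1=n, alpha=alpha, ratio=1.0))
    raise ValueError("method must be 'normal' or 'ttest'")
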