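"""Synthetic ICU cohort generator with known individual treatment effects.

Emulates the statistical structure of an observational sepsis-associated
AKI (S-AKI) cohort in which renal replacement therapy (RRT) is the binary
treatment and 28-day death the binary outcome:

* confounded treatment assignment — sicker patients (higher SOFA,
  creatinine, lactate; lower urine output) are more likely to be treated;
* a heterogeneous, covariate-dependent treatment effect tau(X), entered on
  the survival-probability scale, with benefit concentrated by default in
  patients with low urine output, high lactate and high white-cell count;
* both potential-outcome probabilities stored per record, so downstream
  estimators can be scored against the exact ground truth.

All draws descend from a single seed via :class:`numpy.random.SeedSequence`
spawning, one sub-stream per stage, so a cohort is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "OracleUnavailableError",
    "default_covariate_specs",
    "generate_cohort",
    "true_uplift",
    "write_cohort",
    "read_cohort",
    "SCHEMA_VERSION",
    "REQUIRED_COLUMNS",
]

SCHEMA_VERSION = "1.0"

#: Columns every cohort table must carry to enter the analysis pipeline.
REQUIRED_COLUMNS = (
    "id",
    "treated",
    "died_28d",
    "age",
    "sofa",
    "kdigo_stage",
    "first_icu_admission",
    "esrd",
    "potassium",
)

# Columns present only on synthetic cohorts (the potential-outcome oracle).
ORACLE_COLUMNS = ("p_death_control", "p_death_treated")


class OracleUnavailableError(ValueError):
    """Raised when ground-truth potential outcomes are requested from a
    record that does not carry them (i.e. real data)."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate.

    family:
        ``"normal"`` (params: mean, sd, optional lo/hi clip),
        ``"lognormal"`` (params: mu, sigma of the log),
        ``"categorical"`` (params: levels, probs),
        ``"bernoulli"`` (params: p).
    units: free-text unit label, for documentation and config echo only.
    """

    family: str
    params: Mapping[str, object]
    units: str = ""

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            x = rng.normal(p["mean"], p["sd"], n)
            lo, hi = p.get("lo", -np.inf), p.get("hi", np.inf)
            return np.clip(x, lo, hi)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], n)
        if self.family == "categorical":
            return rng.choice(np.asarray(p["levels"]), size=n, p=p["probs"])
        if self.family == "bernoulli":
            return (rng.random(n) < p["p"]).astype(int)
        raise ValueError(f"unknown covariate family {self.family!r}")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        """Standardize using the *theoretical* moments of the generating
        distribution (log scale for lognormal), so effect coefficients have
        a stable per-SD interpretation independent of the sample drawn."""
        p = self.params
        if self.family == "normal":
            return (x - p["mean"]) / p["sd"]
        if self.family == "lognormal":
            return (np.log(x) - p["mu"]) / p["sigma"]
        if self.family == "categorical":
            levels = np.asarray(p["levels"], dtype=float)
            probs = np.asarray(p["probs"], dtype=float)
            mean = float(levels @ probs)
            sd = float(np.sqrt(probs @ (levels - mean) ** 2))
            return (np.asarray(x, dtype=float) - mean) / (sd if sd > 0 else 1.0)
        if self.family == "bernoulli":
            pr = float(p["p"])
            sd = math.sqrt(pr * (1 - pr)) or 1.0
            return (np.asarray(x, dtype=float) - pr) / sd
        raise ValueError(f"unknown covariate family {self.family!r}")


def default_covariate_specs() -> dict[str, CovariateSpec]:
    """Default first-24h covariate marginals of an S-AKI ICU population.

    Means/SDs follow the published baseline table of the non-treated arm of
    a large MIMIC-III S-AKI cohort; skewed labs and urine volumes are
    log-normal (parameters matched to the reported medians/IQRs), vitals
    normal, ordinal scores categorical.  Creatinine and glucose are fixed in
    mg/dl (converted from the SI values where the source reported SI).
    """
    return {
        "age": CovariateSpec("normal", {"mean": 67.5, "sd": 15.6, "lo": 18.0, "hi": 100.0}, "years"),
        "sofa": CovariateSpec("normal", {"mean": 5.3, "sd": 3.0, "lo": 0.0, "hi": 24.0}, "score"),
        "qsofa": CovariateSpec("categorical", {"levels": [0, 1, 2, 3], "probs": [0.02, 0.18, 0.65, 0.15]}, "score"),
        "kdigo_stage": CovariateSpec(
            "categorical", {"levels": [0, 1, 2, 3], "probs": [0.32, 0.196, 0.376, 0.108]}, "stage"
        ),
        "urine_output": CovariateSpec("lognormal", {"mu": 7.35, "sigma": 0.68}, "ml/24h"),
        "fluid_input": CovariateSpec("lognormal", {"mu": 8.12, "sigma": 0.76}, "ml/24h"),
        "map": CovariateSpec("normal", {"mean": 77.6, "sd": 9.4, "lo": 30.0}, "mmHg"),
        "temperature": CovariateSpec("normal", {"mean": 36.9, "sd": 0.55}, "degC"),
        "heart_rate": CovariateSpec("normal", {"mean": 86.0, "sd": 13.0, "lo": 20.0}, "/min"),
        "resp_rate": CovariateSpec("normal", {"mean": 19.6, "sd": 3.6, "lo": 4.0}, "/min"),
        "spo2": CovariateSpec("normal", {"mean": 96.9, "sd": 2.0, "lo": 50.0, "hi": 100.0}, "%"),
        "lactate": CovariateSpec("lognormal", {"mu": 0.955, "sigma": 0.70}, "mmol/l"),
        "creatinine": CovariateSpec("lognormal", {"mu": 0.124, "sigma": 0.64}, "mg/dl"),
        "wbc": CovariateSpec("lognormal", {"mu": 2.582, "sigma": 0.44}, "1e9/l"),
        "bun": CovariateSpec("lognormal", {"mu": 3.134, "sigma": 0.63}, "mg/dl"),
        "glucose": CovariateSpec("normal", {"mean": 137.3, "sd": 31.7, "lo": 30.0}, "mg/dl"),
        "sodium": CovariateSpec("normal", {"mean": 140.5, "sd": 4.8}, "mmol/l"),
        "chloride": CovariateSpec("normal", {"mean": 108.6, "sd": 6.3}, "mmol/l"),
        "potassium": CovariateSpec("normal", {"mean": 4.79, "sd": 0.74, "lo": 2.0, "hi": 9.0}, "mmol/l"),
        "ph": CovariateSpec("normal", {"mean": 7.43, "sd": 0.07}, "pH"),
        "platelet": CovariateSpec("normal", {"mean": 225.0, "sd": 102.0, "lo": 5.0}, "1e9/l"),
        "sepsis": CovariateSpec("bernoulli", {"p": 1.0}, "flag"),
        "first_icu_admission": CovariateSpec("bernoulli", {"p": 0.92}, "flag"),
        "esrd": CovariateSpec("bernoulli", {"p": 0.03}, "flag"),
    }


#: Covariates entering the standardized severity index that drives
#: confounded treatment assignment (sign: + = sicker when high).
SEVERITY_INDEX = {"sofa": 1.0, "creatinine": 1.0, "lactate": 1.0, "urine_output": -1.0}

_PCLIP = 1e-4  # probability floor/ceiling for potential outcomes


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort draw.

    Parameters
    ----------
    n_patients : cohort size (>= 4).
    treat_fraction_target : marginal treated fraction the assignment model
        is calibrated to hit (by bisection on its intercept).
    confounding_strength : log-odds of treatment per SD of the severity
        index; 0 gives a randomized cohort.
    baseline_mortality_logit : intercept of the control-arm death model.
    mortality_severity_coef : log-odds of death per SD of severity in the
        control arm; >0 makes naive treated-vs-control contrasts biased.
    effect_coefs : per-covariate contribution to the treatment benefit
        tau(X) on the survival-probability scale, per theoretical SD of the
        (log-scale, where lognormal) covariate.
    effect_intercept : constant part of tau(X).
    covariate_spec : marginal distributions; defaults to
        :func:`default_covariate_specs`.
    seed : master seed; sub-streams per stage are spawned from it.
    """

    n_patients: int = 8289
    treat_fraction_target: float = 591 / 8289
    confounding_strength: float = 1.0
    baseline_mortality_logit: float = -1.55
    mortality_severity_coef: float = 0.9
    effect_coefs: dict[str, float] = field(
        default_factory=lambda: {"urine_output": -0.06, "lactate": 0.05, "wbc": 0.04}
    )
    effect_intercept: float = 0.05
    covariate_spec: dict[str, CovariateSpec] = field(default_factory=default_covariate_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0.0 < self.treat_fraction_target < 1.0:
            raise ValueError("treat_fraction_target must be in (0, 1)")
        missing = [v for v in self.effect_coefs if v not in self.covariate_spec]
        if missing:
            raise ValueError(f"effect_coefs refer to covariates not in covariate_spec: {missing}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["covariate_spec"] = {
            k: {"family": s["family"], "params": s["params"], "units": s["units"]}
            for k, s in d["covariate_spec"].items()
        }
        d["schema_version"] = SCHEMA_VERSION
        return json.dumps(d, indent=2, default=float)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _severity_index(df: pd.DataFrame, specs: Mapping[str, CovariateSpec]) -> np.ndarray:
    """Standardized illness-severity score: mean of signed covariate
    z-scores, rescaled to unit theoretical variance."""
    parts = [sign * specs[v].standardize(df[v].to_numpy()) for v, sign in SEVERITY_INDEX.items() if v in df]
    z = np.mean(parts, axis=0)
    # mean of k independent unit-variance terms has sd 1/sqrt(k)
    return z * math.sqrt(len(parts))


def _calibrate_intercept(severity: np.ndarray, slope: float, target: float) -> float:
    """Bisection on the assignment-model intercept so that the expected
    treated fraction equals ``target``."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(_sigmoid(mid + slope * severity).mean())
        if frac < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw one cohort table under ``config``.

    Returns a DataFrame with one row per ICU stay: covariates, ``treated``,
    ``died_28d``, both potential-outcome probabilities and the true uplift
    (control-minus-treated death probability, i.e. benefit on the survival
    scale).  Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_treat, rng_out = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_patients
    specs = config.covariate_spec
    data: dict[str, np.ndarray] = {"id": np.arange(n)}
    for name, spec in specs.items():
        data[name] = spec.draw(n, rng_cov)
    df = pd.DataFrame(data)

    severity = _severity_index(df, specs)

    # --- confounded treatment assignment -------------------------------
    alpha = _calibrate_intercept(severity, config.confounding_strength, config.treat_fraction_target)
    p_treat = _sigmoid(alpha + config.confounding_strength * severity)
    df["treated"] = (rng_treat.random(n) < p_treat).astype(int)

    # --- potential outcomes ---------------------------------------------
    logit_death = config.baseline_mortality_logit + config.mortality_severity_coef * severity
    p_death_control = _sigmoid(logit_death)
    if np.all(p_death_control <= _PCLIP) or np.all(p_death_control >= 1 - _PCLIP):
        raise ValueError(
            "degenerate control death probabilities (all ~0 or ~1); "
            "check baseline_mortality_logit / mortality_severity_coef"
        )

    tau = np.full(n, config.effect_intercept, dtype=float)
    for name, coef in config.effect_coefs.items():
        tau += coef * specs[name].standardize(df[name].to_numpy())

    p_death_treated_raw = p_death_control - tau
    p_death_treated = np.clip(p_death_treated_raw, _PCLIP, 1 - _PCLIP)
    n_clipped = int(np.sum(p_death_treated_raw != p_death_treated))
    if n_clipped:
        warnings.warn(
            f"treatment-effect clipping applied to {n_clipped}/{n} records "
            "to keep death probabilities in [0, 1]",
            RuntimeWarning,
            stacklevel=2,
        )

    df["p_death_control"] = p_death_control
    df["p_death_treated"] = p_death_treated
    df["propensity_true"] = p_treat

    u = rng_out.random(n)
    p_realized = np.where(df["treated"] == 1, p_death_treated, p_death_control)
    df["died_28d"] = (u < p_realized).astype(int)

    # highest KDIGO stage during stay: baseline stage, occasionally
    # progressed by one (never used for treatment/outcome draws)
    progress = (rng_out.random(n) < 0.3) & (df["kdigo_stage"].to_numpy() < 3)
    df["kdigo_stage_highest"] = (df["kdigo_stage"].to_numpy() + progress.astype(int)).clip(max=3)

    return df


def true_uplift(record: pd.DataFrame | pd.Series | Mapping[str, float]) -> np.ndarray | float:
    """Ground-truth individual treatment benefit on the survival scale:
    ``p_death_control - p_death_treated``, in [-1, 1].

    Only defined for synthetic records carrying potential-outcome
    probabilities; raises :class:`OracleUnavailableError` otherwise.
    """
    if isinstance(record, pd.DataFrame):
        missing = [c for c in ORACLE_COLUMNS if c not in record.columns]
    else:
        missing = [c for c in ORACLE_COLUMNS if c not in record]
    if missing:
        raise OracleUnavailableError(
            f"oracle unavailable: record lacks potential-outcome columns {missing} (real data?)"
        )
    if isinstance(record, pd.DataFrame):
        return (record["p_death_control"] - record["p_death_treated"]).to_numpy()
    return float(record["p_death_control"]) - float(record["p_death_treated"])


# --------------------------------------------------------------------------
# cohort table I/O (versioned CSV schema + config echo)
# --------------------------------------------------------------------------

def write_cohort(df: pd.DataFrame, path: str | Path, config: SimConfig | None = None) -> None:
    """Write the cohort as CSV; a sidecar ``<path>.meta.json`` records the
    schema version, column list and (if given) the generating config."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {"schema_version": SCHEMA_VERSION, "columns": list(df.columns)}
    if config is not None:
        meta["config"] = json.loads(config.to_json())
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating the required column set."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    return df
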