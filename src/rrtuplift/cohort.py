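"""Analysis-cohort construction: KDIGO AKI staging and study filters.

The study population is ICU stays meeting sepsis-3 (precomputed flag) with
acute kidney injury (highest KDIGO stage >= 1 during the stay), restricted
to first ICU admissions of adults without end-stage renal disease and
without severe hyperkalaemia (potassium > 6.5 mmol/l, an absolute RRT
indication that would make treatment assignment deterministic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "KdigoInput",
    "KDIGO_THRESHOLDS",
    "kdigo_stage",
    "AttritionLog",
    "apply_cohort_filters",
]


#: Declarative KDIGO staging thresholds (overridable via ``thresholds=``).
#: Creatinine: stage by fold-change over baseline, absolute level, or acute
#: 48h rise; urine output: by sustained oliguria rate; RRT initiation and
#: prolonged anuria are stage 3 by rule.
KDIGO_THRESHOLDS: dict[str, float] = {
    "scr_ratio_stage1": 1.5,
    "scr_ratio_stage2": 2.0,
    "scr_ratio_stage3": 3.0,
    "scr_increase_48h_stage1": 0.3,  # mg/dl
    "scr_absolute_stage3": 4.0,      # mg/dl
    "uo_rate_stage12": 0.5,          # ml/kg/h, over 6h (stage 1) / 12h (stage 2)
    "uo_rate_stage3": 0.3,           # ml/kg/h over 24h
}


@dataclass(frozen=True)
class KdigoInput:
    """Creatinine and urine-output summary of one ICU stay.

    scr_ratio: current / baseline serum creatinine (unitless, > 0)
    scr_increase_48h: absolute creatinine rise within 48 h (mg/dl)
    scr_absolute: current creatinine (mg/dl)
    uo_rate_6h, uo_rate_12h, uo_rate_24h: lowest sustained urine-output
        rate over the given window (ml/kg/h)
    anuria_12h: anuria for >= 12 h
    on_rrt: renal replacement therapy initiated
    """

    scr_ratio: float
    scr_increase_48h: float = 0.0
    scr_absolute: float = 0.0
    uo_rate_6h: float = float("inf")
    uo_rate_12h: float = float("inf")
    uo_rate_24h: float = float("inf")
    anuria_12h: bool = False
    on_rrt: bool = False

    def __post_init__(self) -> None:
        if self.scr_ratio <= 0:
            raise ValueError("scr_ratio must be > 0")
        for name in ("scr_increase_48h", "scr_absolute", "uo_rate_6h", "uo_rate_12h", "uo_rate_24h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def kdigo_stage(k: KdigoInput, thresholds: dict[str, float] | None = None) -> int:
    """AKI stage in {0, 1, 2, 3}: the maximum of the creatinine-based and
    urine-output-based stages; RRT initiation forces stage 3."""
    t = {**KDIGO_THRESHOLDS, **(thresholds or {})}

    if k.on_rrt:
        return 3

    scr = 0
    if k.scr_ratio >= t["scr_ratio_stage3"] or k.scr_absolute >= t["scr_absolute_stage3"]:
        scr = 3
    elif k.scr_ratio >= t["scr_ratio_stage2"]:
        scr = 2
    elif k.scr_ratio >= t["scr_ratio_stage1"] or k.scr_increase_48h >= t["scr_increase_48h_stage1"]:
        scr = 1

    uo = 0
    if k.uo_rate_24h < t["uo_rate_stage3"] or k.anuria_12h:
        uo = 3
    elif k.uo_rate_12h < t["uo_rate_stage12"]:
        uo = 2
    elif k.uo_rate_6h < t["uo_rate_stage12"]:
        uo = 1

    return max(scr, uo)


@dataclass
class AttritionLog:
    """Ordered record of how many rows each cohort filter removed."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (filter, removed, remaining)
    n_input: int = 0

    def add(self, name: str, removed: int, remaining: int) -> None:
        self.steps.append((name, removed, remaining))

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_input

    def validate(self) -> None:
        prev = self.n_input
        for name, removed, remaining in self.steps:
            if remaining != prev - removed or removed < 0:
                raise AssertionError(f"attrition bookkeeping broken at {name!r}")
            prev = remaining

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "steps": [
                    {"filter": n, "removed": rm, "remaining": rem} for n, rm, rem in self.steps
                ],
                "n_final": self.n_final,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"input records: {self.n_input}"]
        for name, removed, remaining in self.steps:
            lines.append(f"  - {name}: removed {removed}, remaining {remaining}")
        lines.append(f"final cohort: {self.n_final}")
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# Filters in the study's reporting order: inclusions first (sepsis, AKI),
# then exclusions (repeat admission, age, ESRD, hyperkalaemia).
_FILTERS: tuple[tuple[str, str], ...] = (
    ("sepsis-3 criteria met", "sepsis"),
    ("AKI: highest KDIGO stage >= 1", "_kdigo"),
    ("first ICU admission", "first_icu_admission"),
    ("age >= 18", "_age"),
    ("no end-stage renal disease", "_esrd"),
    ("potassium <= 6.5 mmol/l", "_potassium"),
)


def apply_cohort_filters(table: pd.DataFrame) -> tuple[pd.DataFrame, AttritionLog]:
    """Apply the study inclusion/exclusion rules, returning the analysis
    cohort and a per-filter attrition log.

    Filters are conjunctive: the retained set is order-independent, only
    the per-filter removal counts depend on the order (which follows the
    study's reporting order).  The AKI filter uses ``kdigo_stage_highest``
    when present, otherwise ``kdigo_stage``.
    """
    kdigo_col = "kdigo_stage_highest" if "kdigo_stage_highest" in table.columns else "kdigo_stage"
    required = {"sepsis", kdigo_col, "first_icu_admission", "age", "esrd", "potassium"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")

    masks = {
        "sepsis": table["sepsis"].astype(bool),
        "_kdigo": table[kdigo_col] >= 1,
        "first_icu_admission": table["first_icu_admission"].astype(bool),
        "_age": table["age"] >= 18,
        "_esrd": ~table["esrd"].astype(bool),
        "_potassium": table["potassium"] <= 6.5,
    }

    log = AttritionLog(n_input=len(table))
    kept = pd.Series(True, index=table.index)
    for name, key in _FILTERS:
        new_kept = kept & masks[key]
        log.add(name, int(kept.sum() - new_kept.sum()), int(new_kept.sum()))
        kept = new_kept
    log.validate()
    return table.loc[kept].copy(), log
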