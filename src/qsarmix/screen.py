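"""Multi-stage screening cascade for designed derivative candidates.

Derivatives are rows of a property table (predicted composite index,
per-enzyme docking scores and their change rates versus the parent,
logKow/logKoc, biodegradability, algal EC50, cyanobacteria docking score,
pLOEC).  A :class:`ScreeningRuleSet` is an ordered list of stages, each a
conjunction of threshold rules on change-rate columns; each stage filters
the survivors of the previous one and every elimination is recorded with
the failing rule and the offending value.

Failed docking runs (printed "/" in the source tables) are stored as NaN and
fail any stage that references them — a derivative that could not dock is
never treated as a zero score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScreeningRule",
    "ScreeningStage",
    "ScreeningRuleSet",
    "ScreeningReport",
    "change_rate",
    "apply_screen",
    "genotoxicity_summary",
]

_OPS = {
    "gt": lambda v, t: v > t,
    "ge": lambda v, t: v >= t,
    "lt": lambda v, t: v < t,
    "le": lambda v, t: v <= t,
}


def change_rate(new_value: float, ref_value: float) -> float:
    """Percent change ``100 * (new - ref) / ref``; NaN input stays flagged.

    Raises on a zero reference; a NaN ``new_value`` (failed measurement)
    propagates as NaN so downstream rules treat it as a failure, never as 0.
    """
    if ref_value == 0:
        raise ValueError("change rate undefined for zero reference value")
    if new_value is None or (isinstance(new_value, float) and math.isnan(new_value)):
        return float("nan")
    return 100.0 * (new_value - ref_value) / ref_value


@dataclass(frozen=True)
class ScreeningRule:
    """One threshold test on a property column (tolerances in percent)."""

    property: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}; use one of {sorted(_OPS)}")
        if not math.isfinite(self.threshold):
            raise ValueError("rule threshold must be finite")

    def passes(self, value: float) -> bool:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False  # failed-docking policy: missing value fails the rule
        return bool(_OPS[self.op](value, self.threshold))

    def describe(self) -> str:
        sym = {"gt": ">", "ge": ">=", "lt": "<", "le": "<="}[self.op]
        return f"{self.property} {sym} {self.threshold:g}"


@dataclass(frozen=True)
class ScreeningStage:
    name: str
    rules: tuple

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError(f"stage {self.name!r} has no rules")
        object.__setattr__(self, "rules", tuple(self.rules))


@dataclass(frozen=True)
class ScreeningRuleSet:
    """Ordered stages; survivors of each stage feed the next."""

    name: str
    stages: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreeningRuleSet":
        stages = tuple(
            ScreeningStage(
                name=s["name"],
                rules=tuple(ScreeningRule(r["property"], r["op"], float(r["threshold"]))
                            for r in s["rules"]),
            )
            for s in d.get("stages", [])
        )
        return cls(name=d.get("name", "custom"), stages=stages)

    @classmethod
    def from_yaml(cls, path) -> "ScreeningRuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "stages": [
                {"name": s.name,
                 "rules": [{"property": r.property, "op": r.op,
                            "threshold": r.threshold} for r in s.rules]}
                for s in self.stages
            ],
        }


@dataclass
class ScreeningReport:
    """Stage-by-stage survivors plus a complete per-derivative audit trail."""

    ruleset: str
    stage_survivors: dict  # stage name -> ordered list of ids
    audit: pd.DataFrame    # id, stage, rule, value, passed
    extras: dict = dc_field(default_factory=dict)

    @property
    def survivors(self) -> list:
        if not self.stage_survivors:
            return []
        return list(self.stage_survivors.values())[-1]

    def failures(self, derivative_id) -> pd.DataFrame:
        a = self.audit
        return a[(a["id"] == derivative_id) & ~a["passed"]]

    def summary(self) -> str:
        lines = [f"Screening cascade '{self.ruleset}'", "=" * 40]
        for stage, ids in self.stage_survivors.items():
            lines.append(f"{stage:<16} {len(ids):>3} survivors: {', '.join(map(str, ids))}")
        for k, v in self.extras.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def apply_screen(
    derivatives: pd.DataFrame,
    rules: ScreeningRuleSet,
    id_column: str = "id",
) -> ScreeningReport:
    """Run the cascade over a derivative property table.

    ``derivatives`` must contain ``id_column`` and every property any stage
    references; NaN entries fail the referencing rule.  Rows whose id equals
    the parent compound (no change rates) should be excluded by the caller.
    """
    if id_column not in derivatives.columns:
        raise ValueError(f"derivative table lacks id column {id_column!r}")
    referenced = {r.property for s in rules.stages for r in s.rules}
    missing = referenced - set(derivatives.columns)
    if missing:
        raise ValueError(f"rule set references unknown properties {sorted(missing)}")

    current = derivatives
    stage_survivors: dict[str, list] = {}
    records = []
    for stage in rules.stages:
        keep = []
        for _, row in current.iterrows():
            ok = True
            for rule in stage.rules:
                value = row[rule.property]
                passed = rule.passes(value)
                records.append({
                    "id": row[id_column], "stage": stage.name,
                    "rule": rule.describe(),
                    "value": float(value) if pd.notna(value) else np.nan,
                    "passed": passed,
                })
                ok = ok and passed
            if ok:
                keep.append(row[id_column])
        stage_survivors[stage.name] = keep
        current = current[current[id_column].isin(keep)]
    audit = pd.DataFrame.from_records(
        records, columns=["id", "stage", "rule", "value", "passed"]
    )
    if not rules.stages:
        stage_survivors = {"(no stages)": list(derivatives[id_column])}
    return ScreeningReport(ruleset=rules.name, stage_survivors=stage_survivors, audit=audit)


def genotoxicity_summary(report: ScreeningReport, geno: pd.DataFrame,
                         id_column: str = "id",
                         change_column: str = "ploec_change") -> ScreeningReport:
    """Annotate a report with genotoxicity change rates of the survivors.

    The genotoxicity endpoint is evaluative, not a hard filter: the report
    gains both the survivor count and the count whose pLOEC increased, since
    the two published candidate-set cardinalities differ.
    """
    surv = report.survivors
    sub = geno[geno[id_column].isin(surv)]
    increased = sub[sub[change_column] > 0][id_column].tolist()
    report.extras["final_survivors"] = len(surv)
    report.extras["genotoxicity_increased"] = len(increased)
    report.extras["genotoxicity_increased_ids"] = increased
    return report
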