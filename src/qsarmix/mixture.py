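"""Mixture toxicity index and combined-action classification.

For a mixture of components with concentrations ``C_i`` and toxicity
references ``T_i`` (an EC50/IC50, or — as in the soil scenarios shipped with
this package — a predicted composite biotoxicity value):

    TU_i = C_i / T_i                        (toxic unit)
    M    = sum_i TU_i
    M0   = M / max_i TU_i
    MTI  = 1 - log(M) / log(M0)

The log base cancels in the ratio (natural log used).  MTI classifies the
combined action: > 1 synergistic, = 1 simple additive, in (0, 1) partial
additive, = 0 independent, < 0 antagonistic.

All arithmetic is carried at full precision; the conventional 3-decimal
rounding is applied only when formatting reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixtureComponent",
    "MixtureScenario",
    "MixtureToxicityResult",
    "toxic_units",
    "mixture_index",
    "classify_action",
    "enumerate_combinations",
    "evaluate_scenario",
    "scenario_report",
    "scenarios_from_frame",
]


@dataclass(frozen=True)
class MixtureComponent:
    """One mixture member: id, concentration (ug/kg) and toxicity reference."""

    id: str
    concentration: float
    toxicity_ref: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.id}: concentration must be >= 0")
        if not self.toxicity_ref > 0:
            raise ValueError(f"{self.id}: toxicity reference must be positive")


@dataclass(frozen=True)
class MixtureScenario:
    """A named environment with its components and one combination of them."""

    environment: str
    components: tuple
    combination: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "combination", tuple(self.combination))
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("component ids must be unique")
        if len(self.combination) < 2:
            raise ValueError("a combination needs at least 2 components")
        unknown = set(self.combination) - set(ids)
        if unknown:
            raise ValueError(f"combination references unknown components {sorted(unknown)}")

    def selected(self) -> tuple:
        by_id = {c.id: c for c in self.components}
        return tuple(by_id[i] for i in self.combination)


@dataclass(frozen=True)
class MixtureToxicityResult:
    environment: str
    combination: tuple
    tu: pd.Series
    m: float
    m0: float
    mti: float
    action: str

    def as_row(self, decimals: int = 3) -> dict:
        row = {"environment": self.environment,
               "combination": "*".join(self.combination)}
        row.update({f"TU_{k}": round(v, decimals) for k, v in self.tu.items()})
        row.update({"M": round(self.m, decimals), "M0": round(self.m0, decimals),
                    "MTI": round(self.mti, decimals), "action": self.action})
        return row


def toxic_units(components: Sequence[MixtureComponent]) -> pd.Series:
    """TU_i = C_i / toxicity_ref_i, indexed by component id."""
    return pd.Series(
        {c.id: c.concentration / c.toxicity_ref for c in components}, dtype=float
    )


def mixture_index(tu: pd.Series | Sequence[float]) -> tuple[float, float, float]:
    """(M, M0, MTI) from a toxic-unit vector.

    Components with TU = 0 are dropped with a warning (they contribute no
    toxic load).  A mixture whose TU mass sits entirely on one component
    (M0 = 1) has an undefined MTI and raises ``"degenerate mixture"``.
    """
    tu = pd.Series(tu, dtype=float)
    if (tu < 0).any():
        raise ValueError("toxic units must be nonnegative")
    if (tu == 0).any():
        warnings.warn("dropping zero-TU components from the mixture", stacklevel=2)
        tu = tu[tu > 0]
    if len(tu) < 2:
        raise ValueError("need at least 2 components with positive toxic units")
    m = float(tu.sum())
    m0 = m / float(tu.max())
    if m0 == 1.0:
        raise ValueError("degenerate mixture: all toxic-unit mass on one component")
    mti = 1.0 - math.log(m) / math.log(m0)
    return m, m0, mti


def classify_action(mti: float, tol: float = 1e-9) -> str:
    """Combined-action class of an MTI value (equalities within ``tol``)."""
    if math.isnan(mti):
        raise ValueError("MTI is NaN")
    if abs(mti - 1.0) <= tol:
        return "simple additive"
    if abs(mti) <= tol:
        return "independent"
    if mti > 1.0:
        return "synergistic"
    if mti > 0.0:
        return "partial additive"
    return "antagonism"


def enumerate_combinations(component_ids: Sequence[str], min_size: int = 2) -> list[tuple]:
    """All subsets of size >= min_size, ordered by size then lexicographically."""
    ids = list(component_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 components to form mixtures")
    out = []
    for size in range(min_size, len(ids) + 1):
        out.extend(sorted(_combinations(sorted(ids), size)))
    return out


def evaluate_scenario(scenario: MixtureScenario, tol: float = 1e-9) -> MixtureToxicityResult:
    """TU/M/M0/MTI and action class for one scenario."""
    tu = toxic_units(scenario.selected())
    m, m0, mti = mixture_index(tu)
    return MixtureToxicityResult(
        environment=scenario.environment, combination=scenario.combination,
        tu=tu, m=m, m0=m0, mti=mti, action=classify_action(mti, tol=tol),
    )


def scenario_report(
    scenarios: Iterable[MixtureScenario], decimals: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate scenarios and summarize the MTI range per environment.

    Returns ``(detail, summary)``: one row per scenario with the rounded
    TU/M/M0/MTI values and action class, and a per-environment min-max MTI
    range with the (unanimous or mixed) action verdict.
    """
    results = [evaluate_scenario(s) for s in scenarios]
    if not results:
        raise ValueError("no scenarios supplied")
    detail = pd.DataFrame([r.as_row(decimals) for r in results])
    tu_cols = sorted(c for c in detail.columns if c.startswith("TU_"))
    lead = ["environment", "combination"]
    detail = detail[lead + tu_cols + ["M", "M0", "MTI", "action"]]

    rows = []
    for env in detail["environment"].unique():
        sub = [r for r in results if r.environment == env]
        mtis = [r.mti for r in sub]
        actions = sorted({r.action for r in sub})
        rows.append({
            "environment": env,
            "combinations": len(sub),
            "mti_min": round(min(mtis), decimals),
            "mti_max": round(max(mtis), decimals),
            "action": actions[0] if len(actions) == 1 else "mixed: " + ", ".join(actions),
        })
    return detail, pd.DataFrame(rows)


def scenarios_from_frame(
    frame: pd.DataFrame,
    combinations: Sequence[Sequence[str]] | str = "all",
) -> list[MixtureScenario]:
    """Build scenarios from a table (environment, label, concentration..., biotoxicity).

    ``combinations`` may be ``"all"`` (every subset of size >= 2 per
    environment) or an explicit list of label tuples.
    """
    required = {"environment", "label", "concentration_ug_per_kg", "biotoxicity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"scenario table lacks columns {sorted(missing)}")
    out = []
    for env, sub in frame.groupby("environment", sort=False):
        comps = tuple(
            MixtureComponent(r["label"], float(r["concentration_ug_per_kg"]),
                             float(r["biotoxicity"]))
            for _, r in sub.iterrows()
        )
        combos = (enumerate_combinations([c.id for c in comps])
                  if combinations == "all" else [tuple(c) for c in combinations])
        out.extend(MixtureScenario(env, comps, combo) for combo in combos)
    return out
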