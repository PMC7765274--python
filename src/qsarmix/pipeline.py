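"""End-to-end orchestration of the evaluation chain.

Stage order mirrors the study workflow: composite index over the parent
score table, derivative screening (both branches), mixture-toxicity replay
over the soil scenarios, binding-energy/MTI concordance, and optionally a
synthetic-data QSAR round trip.  Each stage writes a TSV and/or JSON
artifact into the run directory plus one machine-readable ``summary.json``;
reruns with an unchanged config are bit-identical (the only stochastic
stage, ``qsar``, is seeded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from .composite import CompositeIndexModel, EndpointScoreTable
from .mixture import scenario_report, scenarios_from_frame
from .mmpbsa import concordance
from .qsar import ComfaPLS
from .screen import apply_screen, genotoxicity_summary
from .synthetic import SyntheticQsarSpec, gen_qsar_set

log = logging.getLogger("qsarmix")

KNOWN_STAGES = ("ci", "screen", "mixture", "concordance", "qsar")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "KNOWN_STAGES"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for actionable reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline settings.

    ``stages`` selects which stages run (dependency order is enforced by the
    runner).  ``scores_path`` may point at a molecule-by-endpoint score CSV;
    when omitted the packaged parent table is used.  Unknown keys in
    :meth:`from_dict` are rejected.
    """

    stages: tuple = KNOWN_STAGES[:4]
    scores_path: str | None = None
    scenario_path: str | None = None
    rulesets: tuple = ("enr_default", "spa_default")
    seed: int = 0
    decimals: int = 3
    qsar_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; known: {KNOWN_STAGES}")
        self.stages = tuple(self.stages)
        self.rulesets = tuple(self.rulesets)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        allowed = {"stages", "scores_path", "scenario_path", "rulesets",
                   "seed", "decimals", "qsar_spec"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage_ci(cfg: PipelineConfig, out: Path, summary: dict) -> None:
    if cfg.scores_path:
        table = EndpointScoreTable.from_csv(cfg.scores_path)
    else:
        raw = datasets.load_parent_scores()
        table = EndpointScoreTable(
            raw.set_index("abbrev")[["lds_1b06", "lds_6fpc"]]
        )
    res = CompositeIndexModel(table).fit()
    frame = res.table.as_frame(decimals=cfg.decimals)
    frame.to_csv(out / "ci.tsv", sep="\t")
    summary["ci"] = {
        "weights": dict(zip(res.weights.endpoint_ids, res.weights.weight.tolist())),
        "ci": {str(k): float(v) for k, v in res.ci.items()},
    }


def _stage_screen(cfg: PipelineConfig, out: Path, summary: dict) -> None:
    block = {}
    for rs_name in cfg.rulesets:
        parent = rs_name.split("_")[0].upper()
        table = datasets.load_derivative_table(parent)
        ruleset = datasets.load_ruleset(rs_name)
        report = apply_screen(table, ruleset)
        geno = table[["id", "ploec_change"]]
        report = genotoxicity_summary(report, geno)
        report.audit.to_csv(out / f"screen_{rs_name}_audit.tsv", sep="\t", index=False)
        block[rs_name] = {
            "stage_survivors": report.stage_survivors,
            **report.extras,
        }
    summary["screen"] = block


def _stage_mixture(cfg: PipelineConfig, out: Path, summary: dict) -> None:
    frame = (pd.read_csv(cfg.scenario_path, sep=None, engine="python")
             if cfg.scenario_path else datasets.load_soil_scenarios())
    scenarios = scenarios_from_frame(frame, combinations="all")
    detail, env_summary = scenario_report(scenarios, decimals=cfg.decimals)
    detail.to_csv(out / "mixture_detail.tsv", sep="\t", index=False)
    env_summary.to_csv(out / "mixture_summary.tsv", sep="\t", index=False)
    summary["mixture"] = env_summary.to_dict(orient="records")
    summary["_mixture_detail"] = detail  # handed to the concordance stage


def _stage_concordance(cfg: PipelineConfig, out: Path, summary: dict) -> None:
    energies = datasets.load_binding_energy()
    binding = dict(zip(energies["combination"], energies["g_bind_kcal_mol"]))
    detail = summary.pop("_mixture_detail", None)
    if detail is not None:
        farm = detail[detail["environment"] == "farmland"]
        mti = dict(zip(farm["combination"], farm["MTI"]))
    else:
        mti = dict(zip(energies["combination"], energies["mti"]))
    report = concordance(binding, mti)
    report.table.to_csv(out / "concordance.tsv", sep="\t")
    summary["concordance"] = {
        "strongest_binder": report.strongest_binder,
        "least_toxic": report.least_toxic,
        "coincide": report.coincide,
        "pairwise_agreement": report.pairwise_agreement,
    }


def _stage_qsar(cfg: PipelineConfig, out: Path, summary: dict) -> None:
    spec = SyntheticQsarSpec(**cfg.qsar_spec)
    _, y, info = gen_qsar_set(spec, seed=cfg.seed)
    res = ComfaPLS(info["X"], y, min_sigma=spec.min_sigma).fit()
    (out / "qsar_summary.txt").write_text(res.summary())
    summary["qsar"] = {
        "q2": res.q2, "n_components": res.n_components, "r2": res.r2,
        "see": res.see, "overfit_pct": res.overfit_pct,
        "contributions": res.contributions,
    }


_RUNNERS = {"ci": _stage_ci, "screen": _stage_screen, "mixture": _stage_mixture,
            "concordance": _stage_concordance, "qsar": _stage_qsar}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the selected stages in dependency order; returns the summary.

    Artifacts land in ``out_dir``; the JSON summary is also written there.
    A stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {
        "stages": list(config.stages), "seed": config.seed,
        "rulesets": list(config.rulesets),
    }}
    for stage in KNOWN_STAGES:  # canonical dependency order
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            _RUNNERS[stage](config, out, summary)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(stage, str(exc)) from exc
    summary.pop("_mixture_detail", None)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
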