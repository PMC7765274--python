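"""Packaged reference tables and default screening rule sets.

The published evaluation tables ship with the package as TSV fixtures:
docking scores and composite indices for the 29 parent quinolones, the
ENR/SPA derivative evaluation tables (biotoxicity, environmental behaviour,
genotoxicity), the three-soil concentration scenarios, the printed mixture
reference values and the binding-energy table.  A checksum manifest guards
against silent fixture edits.

Failed docking entries ("/" in the originals) load as NaN; parent rows carry
empty change-rate cells.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .screen import ScreeningRuleSet

__all__ = [
    "load_parent_scores",
    "load_derivative_biotoxicity",
    "load_derivative_environment",
    "load_derivative_genotoxicity",
    "load_derivative_table",
    "load_soil_scenarios",
    "load_mixture_reference",
    "load_binding_energy",
    "load_ruleset",
    "verify_manifest",
]

_DATA = resources.files("qsarmix") / "data"

_NA = ["/", ""]


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=True)


def load_parent_scores() -> pd.DataFrame:
    """29 parent quinolones: two enzyme docking scores + printed CI."""
    return _read("table2_docking_scores.tsv")


def load_derivative_biotoxicity(parent: str | None = None) -> pd.DataFrame:
    """Derivative predicted CI and enzyme docking scores with change rates."""
    df = _read("table4_derivative_biotoxicity.tsv")
    return df if parent is None else df[df["parent"] == parent].reset_index(drop=True)


def load_derivative_environment(parent: str | None = None) -> pd.DataFrame:
    """logKow/logKoc, biodegradability, algal EC50 and cyanobacteria scores."""
    df = _read("table5_environment.tsv")
    return df if parent is None else df[df["parent"] == parent].reset_index(drop=True)


def load_derivative_genotoxicity(parent: str | None = None) -> pd.DataFrame:
    """Predicted pLOEC genotoxicity values with change rates."""
    df = _read("table6_genotoxicity.tsv")
    return df if parent is None else df[df["parent"] == parent].reset_index(drop=True)


def load_derivative_table(parent: str) -> pd.DataFrame:
    """Merged derivative property table for one parent ("ENR" or "SPA").

    Joins the biotoxicity, environment and genotoxicity tables on the
    derivative id; derivatives absent from a later table keep NaN there
    (they were eliminated before that evaluation stage).  The parent's own
    row is excluded — it has no change rates to screen on.
    """
    bio = load_derivative_biotoxicity(parent)
    env = load_derivative_environment(parent).drop(columns=["parent", "name"])
    gen = load_derivative_genotoxicity(parent).drop(columns=["parent", "name"])
    merged = bio.merge(env, on="id", how="left").merge(gen, on="id", how="left")
    return merged[merged["id"] != parent].reset_index(drop=True)


def load_soil_scenarios() -> pd.DataFrame:
    """Residue concentrations and biotoxicity references per soil type."""
    return _read("table7_soil_scenarios.tsv")


def load_mixture_reference() -> pd.DataFrame:
    """Printed M/M0/MTI per combination and soil (replay target)."""
    return _read("table8_mixture_reference.tsv")


def load_binding_energy() -> pd.DataFrame:
    """MMPBSA binding energies per combination with their MTI values."""
    return _read("table10_binding_energy.tsv")


def load_ruleset(name: str) -> ScreeningRuleSet:
    """Packaged screening cascade: ``"enr_default"`` or ``"spa_default"``."""
    with resources.as_file(_DATA / "rules" / f"{name}.yaml") as path:
        return ScreeningRuleSet.from_yaml(path)


def verify_manifest() -> dict:
    """Check fixture SHA-256 sums against the packaged manifest.

    Returns the manifest mapping on success; raises if any file was altered.
    """
    with resources.as_file(_DATA / "manifest.json") as path:
        manifest = json.loads(path.read_text())
    bad = []
    for name, expected in manifest.items():
        with resources.as_file(_DATA / name) as path:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != expected:
            bad.append(name)
    if bad:
        raise RuntimeError(f"fixture checksum mismatch: {bad}")
    return manifest
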