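"""MM/PBSA free-energy bookkeeping and binding-energy/MTI concordance.

End-state binding free energies decompose as

    G      = E_gas - T * S_gas + G_solvation
    E_gas  = E_bond + E_angle + E_dihedral + E_vdw + E_coulomb
    G_solv = G_polar + G_nonpolar
    G_bind = G_complex - G_free_protein - G_free_ligand

with a more negative G_bind meaning tighter binding.  Component energies are
inputs (trajectory post-processing is out of scope); this module is exact
arithmetic over them plus a concordance check between binding energies and
mixture toxicity indices: the mixture binding most strongly (largest
|G_bind|) is expected to carry the smallest MTI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "EnergyComponents",
    "BindingEnergyResult",
    "ConcordanceReport",
    "total_free_energy",
    "binding_energy",
    "concordance",
]


@dataclass(frozen=True)
class EnergyComponents:
    """Gas-phase terms (kcal/mol), temperature (K), entropy (kcal/mol/K),
    and polar/nonpolar solvation terms (kcal/mol) of one species."""

    e_bond: float = 0.0
    e_angle: float = 0.0
    e_dihedral: float = 0.0
    e_vdw: float = 0.0
    e_coulomb: float = 0.0
    temperature: float = 0.0
    s_gas: float = 0.0
    g_polar: float = 0.0
    g_nonpolar: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.e_bond, self.e_angle, self.e_dihedral, self.e_vdw,
                self.e_coulomb, self.temperature, self.s_gas, self.g_polar,
                self.g_nonpolar]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all energy components must be finite")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0 K")

    @property
    def e_gas(self) -> float:
        return (self.e_bond + self.e_angle + self.e_dihedral
                + self.e_vdw + self.e_coulomb)

    @property
    def g_solvation(self) -> float:
        return self.g_polar + self.g_nonpolar


@dataclass(frozen=True)
class BindingEnergyResult:
    g_complex: float
    g_free_protein: float
    g_free_ligand: float

    @property
    def g_bind(self) -> float:
        return self.g_complex - self.g_free_protein - self.g_free_ligand


def total_free_energy(c: EnergyComponents) -> float:
    """G = E_gas - T*S_gas + G_solvation."""
    return c.e_gas - c.temperature * c.s_gas + c.g_solvation


def binding_energy(
    complex_: EnergyComponents,
    protein: EnergyComponents,
    ligand: EnergyComponents,
) -> BindingEnergyResult:
    """Exact end-state difference; more negative = tighter binding."""
    return BindingEnergyResult(
        g_complex=total_free_energy(complex_),
        g_free_protein=total_free_energy(protein),
        g_free_ligand=total_free_energy(ligand),
    )


@dataclass(frozen=True)
class ConcordanceReport:
    """Do the extreme combinations of two rankings coincide?

    ``strongest_binder`` is the combination with the largest |G_bind|,
    ``least_toxic`` the one with the smallest MTI; ``pairwise_agreement`` is
    the fraction of combination pairs ranked concordantly (larger |G_bind|
    together with smaller MTI).
    """

    strongest_binder: str
    least_toxic: str
    coincide: bool
    pairwise_agreement: float
    table: pd.DataFrame

    def summary(self) -> str:
        return (
            f"largest |G_bind|: {self.strongest_binder}   "
            f"smallest MTI: {self.least_toxic}   "
            f"coincide: {self.coincide}   "
            f"pairwise agreement: {self.pairwise_agreement:.2f}"
        )


def concordance(
    binding_table: Mapping[str, float], mti_table: Mapping[str, float]
) -> ConcordanceReport:
    """Compare a G_bind map and an MTI map over the same combinations."""
    keys = list(binding_table)
    if set(keys) != set(mti_table):
        raise ValueError(
            "combination keys differ: "
            f"{sorted(set(keys) ^ set(mti_table))} not shared"
        )
    df = pd.DataFrame({
        "g_bind": [binding_table[k] for k in keys],
        "mti": [mti_table[k] for k in keys],
    }, index=pd.Index(keys, name="combination"))
    df["abs_g_bind"] = df["g_bind"].abs()
    strongest = df["abs_g_bind"].idxmax()
    least = df["mti"].idxmin()
    agree = total = 0
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = df.iloc[i], df.iloc[j]
            dg = a["abs_g_bind"] - b["abs_g_bind"]
            dm = a["mti"] - b["mti"]
            if dg == 0 or dm == 0:
                continue
            total += 1
            agree += (dg > 0) == (dm < 0)
    return ConcordanceReport(
        strongest_binder=str(strongest),
        least_toxic=str(least),
        coincide=strongest == least,
        pairwise_agreement=agree / total if total else 1.0,
        table=df,
    )
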