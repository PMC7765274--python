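"""Grid-based molecular interaction fields for aligned molecule sets.

Steric and electrostatic probe energies are evaluated on a regular lattice
around a set of pre-aligned, pre-charged conformers — the descriptor block of
a CoMFA-style 3D-QSAR.  Conventions follow common CoMFA practice:

* probe: sp3 carbon, charge +1 e;
* steric energy: Lennard-Jones 6-12 sum over atoms,
  ``eps_ij * ((R_ij/r)^12 - 2 (R_ij/r)^6)`` with ``R_ij = r_vdw(atom) +
  r_vdw(probe)`` and ``eps_ij = sqrt(eps_atom * eps_probe)``, truncated above
  at the energy cap (the attractive well, bounded by the pairwise well
  depths, is retained);
* electrostatic energy: Coulomb sum with a distance-dependent dielectric
  (``epsilon = r``), i.e. ``332.0636 * q_p * q_a / r^2`` kcal/mol, clipped
  symmetrically at +/- the cap.

Grid points landing exactly on an atom take the cap, never infinity.
Alignment and charge assignment are inputs, not performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Molecule",
    "AlignedMoleculeSet",
    "ProbeSpec",
    "FieldGridSpec",
    "DescriptorMatrix",
    "compute_fields",
    "VDW_PARAMS",
]

#: Coulomb constant in kcal*A/(mol*e^2).
COULOMB_K = 332.0636

#: (vdW radius in Angstrom, well depth in kcal/mol) per element, Tripos-like.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}


@dataclass(frozen=True)
class Molecule:
    """One aligned conformer: elements, coordinates (A), partial charges (e)."""

    id: str
    elements: tuple
    coords: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        charges = np.asarray(self.charges, dtype=float).ravel()
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", charges)
        n = len(self.elements)
        if n == 0:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if coords.shape[0] != n or charges.shape[0] != n:
            raise ValueError(f"molecule {self.id!r}: inconsistent atom counts")
        if not (np.isfinite(coords).all() and np.isfinite(charges).all()):
            raise ValueError(f"molecule {self.id!r}: non-finite coordinates or charges")
        unknown = set(self.elements) - set(VDW_PARAMS)
        if unknown:
            raise ValueError(f"no van der Waals parameters for elements {sorted(unknown)}")


@dataclass(frozen=True)
class AlignedMoleculeSet:
    """Pre-aligned molecules sharing a common skeleton frame."""

    molecules: tuple
    aligned: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecules", tuple(self.molecules))
        if not self.molecules:
            raise ValueError("empty molecule set")
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        allc = np.vstack([m.coords for m in self.molecules])
        return allc.min(axis=0), allc.max(axis=0)

    @classmethod
    def from_sdf(cls, path, charge_property: str = "PartialCharges") -> "AlignedMoleculeSet":
        """Read an SDF of pre-aligned, pre-charged molecules.

        Partial charges are taken from the named molecule-level SDF property
        (one value per atom, whitespace/comma separated); atom formal charges
        are used as a fallback when the property is absent on every record.
        """
        from rdkit import Chem

        mols = []
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unreadable record {i} in {path}")
            conf = mol.GetConformer()
            coords = conf.GetPositions()
            elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
            if mol.HasProp(charge_property):
                raw = mol.GetProp(charge_property).replace(",", " ").split()
                charges = np.array([float(v) for v in raw])
            else:
                charges = np.array([a.GetFormalCharge() for a in mol.GetAtoms()], float)
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
            mols.append(Molecule(name or f"mol{i}", elements, coords, charges))
        return cls(tuple(mols))


@dataclass(frozen=True)
class ProbeSpec:
    """Probe atom: element (for LJ parameters) and charge in e."""

    element: str = "C"
    charge: float = 1.0

    @property
    def lj(self) -> tuple[float, float]:
        return VDW_PARAMS[self.element]


@dataclass(frozen=True)
class FieldGridSpec:
    """Regular lattice: origin (A), spacing (A), dims (nx, ny, nz)."""

    origin: tuple
    spacing: float = 2.0
    dims: tuple = (5, 5, 5)
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    energy_cap: float = 30.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1")
        if self.energy_cap <= 0:
            raise ValueError("energy cap must be positive")

    @classmethod
    def around(
        cls,
        mols: AlignedMoleculeSet,
        spacing: float = 2.0,
        margin: float = 4.0,
        **kw,
    ) -> "FieldGridSpec":
        """Grid enclosing every atom of ``mols`` with the stated margin."""
        lo, hi = mols.bounds()
        origin = lo - margin
        span = (hi + margin) - origin
        dims = tuple(int(np.ceil(s / spacing)) + 1 for s in span)
        return cls(origin=tuple(origin), spacing=spacing, dims=dims, **kw)

    def points(self) -> np.ndarray:
        """All lattice points, x fastest-varying last (C order), shape (N, 3)."""
        axes = [
            np.asarray(self.origin)[k] + self.spacing * np.arange(self.dims[k])
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))


@dataclass(frozen=True)
class DescriptorMatrix:
    """Molecules x (grid point, field type) energy matrix in kcal/mol.

    ``columns`` carries per-column metadata (field type and grid coordinates);
    ``dropped`` records columns removed by any downstream filter so that no
    column ever disappears silently.
    """

    values: pd.DataFrame
    columns: pd.DataFrame
    grid: FieldGridSpec
    dropped: tuple = ()

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def field_types(self) -> np.ndarray:
        return self.columns["field"].to_numpy()

    def filtered(self, min_sigma: float) -> "DescriptorMatrix":
        """Drop columns with std below ``min_sigma`` (kcal/mol), recorded."""
        std = self.values.std(axis=0, ddof=1).to_numpy()
        keep = std >= min_sigma
        dropped = tuple(self.values.columns[~keep])
        return replace(
            self,
            values=self.values.loc[:, keep],
            columns=self.columns.loc[keep],
            dropped=self.dropped + dropped,
        )


def compute_fields(mols: AlignedMoleculeSet, grid: FieldGridSpec) -> DescriptorMatrix:
    """Steric and electrostatic probe energies for every molecule and node.

    Deterministic for fixed inputs.  Columns are ordered steric block first,
    then electrostatic, each in grid-point order.
    """
    pts = grid.points()
    cap = grid.energy_cap
    r_probe, eps_probe = grid.probe.lj
    q_probe = grid.probe.charge

    n_pts = len(pts)
    steric = np.empty((len(mols), n_pts))
    electro = np.empty((len(mols), n_pts))
    for mi, mol in enumerate(mols):
        R = np.array([VDW_PARAMS[el][0] for el in mol.elements]) + r_probe
        eps = np.sqrt(np.array([VDW_PARAMS[el][1] for el in mol.elements]) * eps_probe)
        # (n_pts, n_atoms) distances
        d = np.linalg.norm(pts[:, None, :] - mol.coords[None, :, :], axis=2)
        d = np.maximum(d, 1e-12)
        ratio6 = (R[None, :] / d) ** 6
        steric[mi] = np.minimum((eps[None, :] * (ratio6**2 - 2.0 * ratio6)).sum(axis=1), cap)
        electro[mi] = np.clip(
            (COULOMB_K * q_probe * mol.charges[None, :] / d**2).sum(axis=1), -cap, cap
        )

    ix, iy, iz = np.unravel_index(np.arange(n_pts), grid.dims)
    block = pd.DataFrame({"ix": ix, "iy": iy, "iz": iz,
                          "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]})
    meta = pd.concat(
        [block.assign(field="steric"), block.assign(field="electrostatic")],
        ignore_index=True,
    )
    names = [f"{f[0]}{i}" for f, blk in (("steric", 0), ("electrostatic", 1))
             for i in range(n_pts)]
    meta.index = pd.Index(names, name="column")
    values = pd.DataFrame(np.hstack([steric, electro]), index=pd.Index(mols.ids),
                          columns=meta.index)
    return DescriptorMatrix(values=values, columns=meta, grid=grid)
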