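"""Seeded generators for every input class the pipeline consumes.

Three generators emulate the statistical structure of the real inputs — not
their chemistry:

* :func:`gen_score_matrix` — molecules x endpoints docking-score matrices
  with controllable column means and coefficients of variation.  Defaults
  mirror the published two-enzyme table: 29 molecules, means near 66 score
  units, CVs near 0.09 (which is what makes the two endpoint weights come
  out almost 1:1).
* :func:`gen_qsar_set` — aligned conformer sets built by perturbing a rigid
  mock scaffold, with an activity that is exactly linear in the computed
  field descriptors plus Gaussian noise; the true coefficient vector is
  returned for recovery tests.
* :func:`gen_mixture_scenarios` — per-environment concentration/toxicity
  tables like the three-soil scenario fixture (concentrations sub-ug/kg,
  toxicity references near 1).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composite import EndpointScoreTable
from .fields import AlignedMoleculeSet, FieldGridSpec, Molecule, compute_fields

__all__ = [
    "ScoreMatrixSpec",
    "SyntheticQsarSpec",
    "gen_score_matrix",
    "gen_qsar_set",
    "gen_mixture_scenarios",
    "default_scaffold",
]


@dataclass(frozen=True)
class ScoreMatrixSpec:
    """Target structure of a synthetic docking-score matrix."""

    n_molecules: int = 29
    means: tuple = (66.3, 65.4)
    cvs: tuple = (0.087, 0.091)
    endpoint_ids: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("need at least 2 molecules")
        if len(self.means) != len(self.cvs):
            raise ValueError("means and cvs must have equal length")
        if any(m <= 0 for m in self.means):
            raise ValueError("target means must be positive")
        if any(v < 0 for v in self.cvs):
            raise ValueError("target CVs must be >= 0")


def gen_score_matrix(spec: ScoreMatrixSpec, seed: int) -> EndpointScoreTable:
    """Gaussian score columns hitting the target means/CVs in expectation.

    If a target CV is large enough that negative scores become likely
    (mean - 3*sigma < 0) the column is drawn from a zero-truncated normal
    instead, with a warning (sample moments then deviate slightly).
    """
    rng = np.random.default_rng(seed)
    cols = {}
    endpoint_ids = spec.endpoint_ids or tuple(
        f"E{j + 1}" for j in range(len(spec.means))
    )
    for eid, mean, cv in zip(endpoint_ids, spec.means, spec.cvs):
        sigma = mean * cv
        if sigma == 0:
            cols[eid] = np.full(spec.n_molecules, mean)
        elif mean - 3 * sigma < 0:
            warnings.warn(
                f"endpoint {eid}: CV {cv} risks negative scores; "
                "drawing from a zero-truncated normal", stacklevel=2
            )
            a = (0 - mean) / sigma
            cols[eid] = stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sigma,
                size=spec.n_molecules, random_state=rng,
            )
        else:
            cols[eid] = rng.normal(mean, sigma, size=spec.n_molecules)
    index = pd.Index([f"M{i + 1}" for i in range(spec.n_molecules)], name="molecule")
    return EndpointScoreTable(pd.DataFrame(cols, index=index))


# ---------------------------------------------------------------------------
# synthetic aligned conformers

def default_scaffold() -> Molecule:
    """A rigid 9-atom mock scaffold: fused-ring-like carbon frame with one
    nitrogen, one oxygen and one fluorine carrying partial charges."""
    elements = ("C", "C", "C", "C", "C", "C", "N", "O", "F")
    coords = np.array([
        [0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [2.1, 1.2, 0.0],
        [1.4, 2.4, 0.0], [0.0, 2.4, 0.0], [-0.7, 1.2, 0.0],
        [3.5, 1.2, 0.3], [-0.7, 3.6, -0.3], [2.1, 3.6, 0.2],
    ])
    charges = np.array([-0.05, -0.05, 0.10, 0.10, -0.05, -0.05, -0.40, -0.45, -0.20])
    return Molecule("scaffold", elements, coords, charges)


@dataclass(frozen=True)
class SyntheticQsarSpec:
    """World for field-descriptor recovery experiments.

    Molecules vary along ``n_modes`` shared deformation modes with
    per-molecule latent coefficients drawn N(0, 1) and truncated at
    ``latent_clip`` — a designed derivative series spans a bounded
    substituent range rather than arbitrary geometry.  ``perturbation``
    scales the coordinate modes (A per unit latent, RMS per coordinate);
    ``charge_jitter`` (e) scales the charge modes.  ``n_signal`` descriptor
    columns — the ones responding most linearly to the latent modes —
    carry the true coefficients; ``noise_sigma`` is the activity noise
    relative to the unit-variance noiseless activity.
    """

    n_molecules: int = 16
    scaffold: Molecule = field(default_factory=default_scaffold)
    perturbation: float = 0.10
    charge_jitter: float = 0.08
    n_modes: int = 3
    latent_clip: float = 1.5
    n_signal: int = 3
    noise_sigma: float = 0.05
    grid_spacing: float = 2.0
    grid_margin: float = 3.0
    min_sigma: float = 2.0
    null_model: bool = False

    def __post_init__(self) -> None:
        if self.perturbation < 0 or self.noise_sigma < 0:
            raise ValueError("perturbation and noise_sigma must be >= 0")
        if self.n_molecules < 4:
            raise ValueError("need at least 4 molecules")
        if self.n_modes < 1:
            raise ValueError("need at least 1 deformation mode")


def gen_qsar_set(spec: SyntheticQsarSpec, seed: int):
    """Perturbed-scaffold conformers plus a field-linear activity.

    Returns ``(mols, y, info)`` where ``info`` holds the descriptor matrix
    ``X`` (unfiltered), the signal column names, the true coefficients and
    the latent deformation coefficients.  With ``null_model=True`` the
    activity is pure noise (no field signal).
    """
    rng = np.random.default_rng(seed)
    base = spec.scaffold
    # Molecules vary along a few shared deformation modes (a derivative
    # series changes along substituent axes, not by independent jitter of
    # every atom); this keeps the descriptor matrix low-rank enough for
    # leave-one-out validation to be meaningful at small n.
    coord_modes = rng.normal(0, 1, (spec.n_modes, *base.coords.shape))
    coord_modes /= np.linalg.norm(coord_modes, axis=(1, 2), keepdims=True)
    charge_modes = rng.normal(0, 1, (spec.n_modes, base.charges.shape[0]))
    charge_modes /= np.linalg.norm(charge_modes, axis=1, keepdims=True)
    latents = np.clip(
        rng.normal(0, 1, (spec.n_molecules, spec.n_modes)),
        -spec.latent_clip, spec.latent_clip,
    )
    scale = spec.perturbation * np.sqrt(base.coords.size)
    mols = []
    for i in range(spec.n_molecules):
        t = latents[i]
        coords = base.coords + scale * np.tensordot(t, coord_modes, axes=1)
        charges = base.charges + spec.charge_jitter * (t @ charge_modes)
        mols.append(Molecule(f"S{i + 1}", base.elements, coords, charges))
    molset = AlignedMoleculeSet(tuple(mols))
    grid = FieldGridSpec.around(molset, spacing=spec.grid_spacing, margin=spec.grid_margin)
    X = compute_fields(molset, grid)

    V = X.values.to_numpy()
    std = V.std(axis=0, ddof=1)
    # Signal must live on smooth descriptors: columns pinned at the energy
    # cap for any molecule are saturated step functions, not linear signal;
    # among the rest, prefer the columns best explained linearly by the
    # latent modes (R2 of column ~ latents).
    unclipped = (np.abs(V) < 0.999 * grid.energy_cap).all(axis=0)
    ok = (std >= spec.min_sigma) & unclipped
    if ok.sum() < spec.n_signal:
        raise ValueError(
            "not enough smooth high-variance descriptor columns for the "
            "requested signal; increase perturbation or lower min_sigma"
        )
    design = np.column_stack([np.ones(spec.n_molecules), latents])
    coef, *_ = np.linalg.lstsq(design, V, rcond=None)
    resid_var = (V - design @ coef).var(axis=0)
    r2_latent = 1.0 - resid_var / np.maximum(V.var(axis=0), 1e-12)
    score = np.where(ok, r2_latent, -np.inf)
    idx = np.argsort(-score)[: spec.n_signal]
    signal_cols = list(X.values.columns[idx])
    beta = rng.uniform(0.5, 1.5, size=spec.n_signal) * rng.choice([-1, 1], spec.n_signal)
    # scale coefficients so the noiseless activity has unit standard deviation
    raw = V[:, idx] @ beta
    if raw.std(ddof=1) > 0:
        beta = beta / raw.std(ddof=1)
    if spec.null_model:
        y = rng.normal(0.0, 1.0, size=spec.n_molecules)
        beta = np.zeros_like(beta)
    else:
        y = V[:, idx] @ beta + rng.normal(0.0, spec.noise_sigma, size=spec.n_molecules)
    info = {"X": X, "signal_columns": signal_cols, "beta_true": beta,
            "grid": grid, "latents": latents}
    return molset, y, info


# ---------------------------------------------------------------------------
# synthetic mixture scenarios

def gen_mixture_scenarios(
    n_components: int = 4,
    concentration_range: tuple = (0.05, 0.8),
    toxicity_range: tuple = (0.8, 1.1),
    environments: tuple = ("farmland", "garden", "woodland"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-environment component tables like the three-soil fixture.

    Each environment draws one shared concentration (the fixture applies one
    residue level per soil to all compounds) and per-compound toxicity
    references.  Feed the result to
    :func:`qsarmix.mixture.scenarios_from_frame`.
    """
    if n_components < 2:
        raise ValueError("need at least 2 components")
    lo_c, hi_c = concentration_range
    lo_t, hi_t = toxicity_range
    if not (0 < lo_c <= hi_c and 0 < lo_t <= hi_t):
        raise ValueError("ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    labels = [chr(ord("A") + i) for i in range(n_components)]
    rows = []
    for env in environments:
        conc = rng.uniform(lo_c, hi_c)
        for lab in labels:
            rows.append({
                "environment": env,
                "label": lab,
                "compound": f"synthetic-{lab}",
                "concentration_ug_per_kg": conc,
                "biotoxicity": rng.uniform(lo_t, hi_t),
            })
    return pd.DataFrame(rows)
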