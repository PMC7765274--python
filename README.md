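# qsarmix

Quinolone (fluoroquinolone) antibiotics accumulate in agricultural soils and
stress non-target plants such as perennial ryegrass.  One computational route
to "greener" quinolones scores each candidate molecule against the plant's
stress-response enzymes (superoxide dismutase and a Pro–Pro endopeptidase) by
docking, fuses the per-enzyme scores into a single biotoxicity index, models
that index with a field-based 3D-QSAR to find modification sites, screens
designed derivatives on environmental and functional criteria, and finally
asks how mixtures of the surviving derivatives behave in real soils.

`qsarmix` implements that chain as a tested Python library with a thin CLI,
for computational toxicologists and cheminformaticians who want the
statistical machinery without the commercial modelling stack.  Docking
scores, partial charges, property predictions and MD component energies are
*inputs*; everything downstream of them is computed here.

## The statistics at the core

**Composite biotoxicity index (CV weighting).** For a molecules × endpoints
docking-score matrix `X`, each endpoint `j` gets weight
`w_j = cv_j / Σ_k cv_k` with `cv_j = σ_j / x̄_j` (population σ).  Per
molecule, `CI_i = Σ_j (X_ij / x̄_j) · w_j`; a molecule scoring at every
column mean has CI = 1, and CI is invariant to rescaling any endpoint.

**Field-PLS QSAR.** Steric (Lennard-Jones) and electrostatic (Coulomb,
distance-dependent dielectric) probe energies on a lattice around aligned
conformers, capped at ±30 kcal/mol, regressed on the activity by partial
least squares.  Validation: leave-one-out `q² = 1 − PRESS/SS_tot`, fitted
`R²`, `SEE = √(SS_res/(n−c−1))`, `F`, overfit ratio `(R²−q²)/R²`, external
`r²_pred` about the training mean, field contribution fractions from
|coefficient|·σ, progressive y-scrambling (Q², cSDEP, dq²/dr²yy′), and
stdev·coeff contour regions with the green/yellow/blue/red reading.

**Mixture toxicity index.** Toxic units `TU_i = C_i / T_i`, `M = Σ TU`,
`M0 = M / max TU`, `MTI = 1 − log M / log M0`; MTI > 1 synergistic, 1
additive, (0,1) partial additive, 0 independent, < 0 antagonistic.

**MM/PBSA bookkeeping.** `G = E_gas − T·S_gas + G_solv` per species and
`G_bind = G_complex − G_protein − G_ligand`, plus a concordance check that
the strongest-binding mixture is the least toxic one.

## Worked example

The packaged 29×2 docking-score table, fused:

```python
>>> from qsarmix import datasets, CompositeIndexModel
>>> raw = datasets.load_parent_scores()
>>> res = CompositeIndexModel(raw.set_index("abbrev")[["lds_1b06", "lds_6fpc"]]).fit()
>>> print(res.summary())
Composite biotoxicity index (CV weighting)
============================================
molecules: 29   endpoints: 2

Endpoint weights:
             mean     std      cv  weight
lds_1b06  66.2566  5.7347  0.0866  0.4887
lds_6fpc  65.4103  5.9224  0.0905  0.5113
...
```

The two enzymes end up weighted almost 1:1 (0.489 / 0.511) because their
score columns have nearly equal coefficients of variation; enrofloxacin's
composite index comes out 1.076, i.e. about 8% above the cohort mean of 1 —
one of the most biotoxic parents, which is why it is a modification target.

Soil mixtures of enrofloxacin (A) and three of its designed derivatives
(B, C, D):

```python
>>> from qsarmix import scenarios_from_frame, scenario_report
>>> detail, summary = scenario_report(scenarios_from_frame(datasets.load_soil_scenarios()))
>>> print(detail[detail.environment == "farmland"].head(3).to_string(index=False))
environment combination  TU_A  TU_B  TU_C  TU_D     M    M0   MTI           action
   farmland         A*B 0.723 0.901   NaN   NaN 1.624 1.803 0.177 partial additive
   farmland         A*C 0.723   NaN  0.88   NaN 1.604 1.821 0.212 partial additive
   farmland         A*D 0.723   NaN   NaN 0.885 1.609 1.817 0.204 partial additive
```

At farmland residue levels every combination is partial-additive
(0 < MTI < 1) and the quaternary mixture is the least toxic (MTI 0.079); at
the lower garden/woodland levels all combinations turn synergistic
(MTI > 1).

The same chain from a shell:

```bash
qsarmix ci                       # composite index over the packaged table
qsarmix screen --rules enr_default
qsarmix mixture
qsarmix mmpbsa
qsarmix run --out runs/demo     # all stages + summary.json
```

## Screening cascades

`qsarmix screen` applies ordered rule stages (YAML-configurable) to
derivative property tables.  The packaged `enr_default` cascade keeps
derivatives whose SOD docking score rose and whose PPEP-2 score fell by at
most 6%, then requires reduced logKow and logKoc, then an increased
cyanobacteria docking score; `spa_default` requires strictly increased
scores on both enzymes and the same environmental stage.  Every eliminated
derivative carries an audit record naming the failing rule and value.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged input tables and the library code alone, the
composite biotoxicity index of enrofloxacin (t1) and the mixed toxicity
indices of six benchmark soil mixtures (t2–t7), writing one
`{"value": ..., "n": ...}` entry per target id.

See `docs/methods.md` for model assumptions, parameter defaults, synthetic
data design and known limitations.
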