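# Methods

This note records the models implemented in `qsarmix`, their assumptions,
the defaults that matter, and what the synthetic generators do and do not
establish.

## Composite biotoxicity index

The coefficient-of-variation weighting treats each docking endpoint
(receptor enzyme) as one criterion in a multi-criteria score.  For the
molecules × endpoints matrix `X`:

- column mean `x̄_j` and **population** standard deviation `σ_j`
  (divisor `n`, not `n−1` — the weighting is descriptive, not inferential;
  weight ratios are nearly insensitive to the choice, but the population
  form is implemented exactly);
- `cv_j = σ_j / x̄_j`, `w_j = cv_j / Σ cv`;
- individual index `H_ij = X_ij / x̄_j` and `CI_i = Σ_j H_ij w_j`.

The denominator of `H` is the column mean.  That choice is the only reading
under which the packaged 29×2 score table reproduces its published CI column
(to within a uniform ≈0.65% offset; see *Known discrepancies*).  The
denominator is exposed as an argument so sensitivity to other normalizers
can be probed.

Consequences used as test invariants: `CI = 1` for a molecule at every
column mean, mean of `H` per endpoint is 1, weighted cohort mean of CI is 1,
and CI is invariant to rescaling any single endpoint column (docking scores
have arbitrary scale, so this invariance is essential).

Molecules with missing scores are rejected, not imputed: the weighting has
no natural missing-data semantics and silently zero-filling a docking score
would masquerade as a real (terrible) score.

## Field descriptors and PLS QSAR

Grid fields follow common CoMFA conventions, all configurable:

| parameter | default | why |
| --- | --- | --- |
| probe | sp³ carbon, +1 e | the standard CoMFA probe |
| spacing | 2.0 Å | standard lattice resolution |
| margin | 4.0 Å | grid box beyond the union of atoms |
| energy cap | ±30 kcal/mol | bounds the r→0 singularities |
| column drop | σ < 2.0 kcal/mol | the usual minimum-sigma filter |

Steric energy is a Lennard-Jones 6-12 sum
(`ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶]`, `R_ij` = sum of van der Waals radii,
`ε_ij` geometric mean) truncated **above** at the cap; the attractive well
is retained (its magnitude is bounded by the pairwise well depths, well
under 1 kcal/mol per atom pair).  Electrostatic energy is a Coulomb sum with
the distance-dependent dielectric `ε(r) = r`, i.e. `332.0636·q_p·q_a/r²`,
clipped symmetrically.  A grid node coinciding with an atom receives the
cap, never infinity.  Flipping all partial charges negates the
electrostatic block exactly (up to the clip boundary), which tests exploit.

PLS is scikit-learn's NIPALS with centring only (no autoscaling — the
CoMFA convention, since all columns share kcal/mol units).  The validation
battery:

- `q²` by explicit leave-one-out: `1 − PRESS/SS_tot`, `SS_tot` about the
  full training mean; the optimal component count is the smallest `c`
  attaining the maximal `q²` within a cap (default 6, never more than
  `n−2` so every fold remains fittable);
- `R²`, `SEE = √(SS_res/(n−c−1))`,
  `F = (R²/c)/((1−R²)/(n−c−1))` — the standard textbook forms.  The
  commercial package's exact F convention is not published; no attempt is
  made to force agreement with its printed values;
- overfit ratio `(R²−q²)/R²·100%` (< 25% is the customary screen);
- external `r²_pred = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)²` over held-out molecules —
  about the *training* mean, so it may be negative;
- field contributions: per-field share of `Σ |coefficient|·σ_column`;
- progressive y-scrambling: a random subset of the response is permuted at
  increasing fractions, `q²` and `SDEP = √(PRESS/n)` are tracked against
  the scrambled-to-original `r²_yy'`, both are fitted quadratically, and
  Q²/cSDEP are the fits evaluated at the critical point (0.85 by
  convention) with `dq²/dr²yy'` the fitted slope there.  This is
  methodology-compatible with, not bit-compatible to, the commercial
  progressive-scrambling implementation, whose internals are unpublished.

Contour regions rank columns by `σ·coefficient`.  The top 80% of the
absolute mass (configurable) is the "support" set drawn on contour maps.
Colors follow the CoMFA reading with activity = biotoxicity: green
(steric, positive) — bulk raises toxicity, small substituents nearby reduce
it; yellow (steric, negative) — large substituents reduce it; blue
(electrostatic, positive) — negative groups reduce it; red (electrostatic,
negative) — positive groups reduce it.

Training/test splits are caller-supplied; a seeded uniform splitter is
provided.  The published 11/4 split membership is unknown, so no attempt is
made to reproduce the published q²/R²/SEE/F/r²_pred values — the original
aligned structures are not available either.  Those numbers enter only as
the arithmetic identity check `(0.996−0.767)/0.996 = 22.992%`.

## Derivative screening

A screening cascade is an ordered list of stages, each a conjunction of
threshold rules on change-rate columns (`100·(new−ref)/ref`).  Failed
docking entries ("/" in the source tables) are NaN and fail any rule that
references them — a molecule that could not dock must not be treated as
scoring zero.

The packaged ENR cascade uses a **−6% tolerance** on the PPEP-2 change
rate.  The published survivor list is described as "increased or remained
constant", yet contains a derivative at −5.57% and excludes the next
candidate at −7.90%; −6% is the reverse-engineered boundary that reproduces
the published set and is prominently configurable.  The SPA cascade
requires strictly positive change on both enzymes and has no cyanobacteria
stage — the published workflow treats the two branches asymmetrically.

The algal-toxicity columns follow the source's reading, where a *larger*
EC50 change rate is reported as a *stronger* algal effect; note this
inverts the conventional meaning of EC50 (higher EC50 = less potent).  The
columns are carried as data and not used in the default cascades.

Genotoxicity (pLOEC) is an evaluative annotation, not a hard filter: the
source reports both "3 + 5 derivatives" and "four environmentally friendly
derivatives" for the final set, so the report carries the survivor count
and the genotoxicity-increased count side by side and asserts neither.

Loosening any rule threshold can only grow a survivor set (stages are
conjunctions applied to the previous stage's survivors); this monotonicity
is a test property.

## Mixture toxicity

`TU_i = C_i/T_i`, `M = Σ TU`, `M0 = M/max TU`, `MTI = 1 − log M/log M0`.
The toxicity reference `T_i` is caller-supplied: an EC50/IC50 where
measured, or — as in the packaged soil scenarios — the predicted composite
biotoxicity value (the reading under which the packaged concentration table
reproduces the published TU/M/M0/MTI block exactly).  The logarithm base
cancels; natural log is used.  All arithmetic is full-precision with
3-decimal rounding only at the formatting boundary: the published table's
`M = 3.390` for the farmland quaternary mixture only emerges from
full-precision TUs rounded at the end.

Zero-TU components are dropped with a warning; a mixture whose TU mass sits
on one component (`M0 = 1`) has an undefined MTI and raises.  For equal TUs
`t` across `n` components, `M0 = n` and `MTI = 1 − log(nt)/log n`; scaling
all concentrations by `c` leaves `M0` fixed and shifts MTI by
`−log c/log M0` — both closed forms are test invariants.

Classification (with a configurable equality tolerance, default 1e-9):
MTI > 1 synergistic, = 1 simple additive, (0,1) partial additive,
= 0 independent, < 0 antagonism.

## MM/PBSA bookkeeping

`E_gas = E_bond + E_angle + E_dihedral + E_vdw + E_coulomb`,
`G_solv = G_polar + G_nonpolar`, `G = E_gas − T·S_gas + G_solv`,
`G_bind = G_complex − G_protein − G_ligand`.  Component energies are
inputs; trajectory generation, PB/SA solving and entropy estimation are out
of scope.  The module is exact arithmetic (additivity in every component is
tested as an identity), plus a concordance report: the combination with the
largest |G_bind| versus the one with the smallest MTI, and the fraction of
combination pairs ranked concordantly.

## Synthetic data

The generators emulate the *statistical structure* of the real inputs, not
their chemistry.  A green test on synthetic data establishes that the
estimators recover known structure under the stated noise model; it says
nothing about docking accuracy, conformer quality or real soil chemistry.

**Score matrices** draw Gaussian columns with target means and CVs
(defaults: 29 molecules, means ≈ 66 score units, CVs ≈ 0.09 — the regime of
the packaged table, which is what makes the two endpoint weights come out
near 1:1).  If a requested CV makes negative scores likely, a
zero-truncated normal is used with a warning.

**QSAR sets** perturb a rigid 9-atom mock scaffold along **3 shared
deformation modes** with per-molecule latent coefficients ~N(0,1) truncated
at ±1.5, coordinate scale 0.10 Å·√dof per unit latent, charge scale 0.08 e
(16 molecules by default).  A derivative series in practice varies along a
few substituent axes, and this low intrinsic dimension is also structurally
necessary: with independent per-atom jitter the molecule set's intrinsic
dimension exceeds any small sample size and leave-one-out validation of a
field-linear activity cannot succeed even at zero noise.  The activity is
exactly `X·β` on the few descriptor columns that respond most linearly to
the latents (cap-saturated columns are excluded — a clipped column is a
step function, not linear signal), plus Gaussian noise (default σ = 0.05 of
the unit-variance clean activity).  The true β is returned for recovery
tests.  Measured behaviour at these defaults: noiseless LOO q² ≥ 0.95 on
seeds 0–9; low-noise q² ≥ 0.95; null-model (pure-noise activity) q² is
negative in the vast majority of seeds with a measured tail
P(q² > 0.3) ≈ 1% — the test suite pins canonical seeds 0–9, where the
bound holds.

**Mixture scenarios** draw one shared residue concentration per environment
(as in the packaged soil table) and per-compound toxicity references from
stated ranges.

All generators are pure functions of (spec, seed).

## Numerical choices and degenerate inputs

- Population (divisor-`n`) std in the weighting; sample (ddof = 1) std in
  descriptor filtering and contributions, matching each context's
  convention.
- All-constant score columns → "degenerate weights" error; zero column mean
  → "cv undefined" error; constant activity → fit error; `n − c − 1 ≤ 0` →
  SEE/F error; perfect fit → SEE 0 and F reported as +inf.
- Component-count ties in the q² scan break toward the smaller count.
- TU maxima need no tie-breaking (`max` is well defined under ties).
- Reports round at 3 decimals; JSON artifacts carry full precision.

## Known discrepancies and limitations

- Applying the weighting equations literally to the packaged 29×2 table
  gives CI values a uniform ≈0.65% above the published column (factor
  ≈ 1.0065 on every molecule).  The source's unstated variant (possibly
  column means over a larger molecule set, or intermediate rounding) is not
  chased; the literal equations are implemented and the offset documented.
- One published change rate (ENR derivative D-1, PPEP-2: −22.93%) is
  inconsistent with its own tabulated scores (→ −29.92%); the fixture keeps
  the printed value, and the derivative is eliminated by the cascade under
  either number.
- The published F = 614.264 is not reproducible from the standard F formula
  at the printed R², n and c; the originating convention is unknown and no
  agreement is forced.
- Published binding energies come from MD trajectories that are out of
  scope; they are fixtures for the concordance check only.
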