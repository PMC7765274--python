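"""PLS regression on molecular-field descriptors with full validation.

The model regresses an activity (here the composite biotoxicity index) on
grid-field descriptors with partial least squares and reports the validation
battery customary for CoMFA models:

* leave-one-out cross-validated ``q2 = 1 - PRESS / SS_tot`` and the optimal
  latent-component count ``n`` (smallest count attaining the maximal q2),
* non-cross-validated ``R2``, standard error of estimate
  ``SEE = sqrt(SS_res / (n - c - 1))`` and
  ``F = (R2/c) / ((1 - R2)/(n - c - 1))`` with ``c`` latent components,
* the overfit ratio ``(R2 - q2)/R2`` as a percentage (< 25% is the usual
  no-overfitting screen),
* external ``r2_pred`` about the *training* mean,
* per-field contribution fractions from ``|coefficient| * column std``,
* progressive y-scrambling statistics (Q2, cSDEP, dq2/dr2yy'), and
* stdev*coeff contour regions with the green/yellow/blue/red reading used to
  pick sites where substituents reduce the activity.

PLS itself is scikit-learn's NIPALS (centring only, no autoscaling, the
CoMFA convention); everything around it is implemented here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .fields import DescriptorMatrix

__all__ = [
    "ComfaPLS",
    "ComfaResults",
    "ScramblingReport",
    "fit_pls",
    "loo_q2",
    "select_optimal_components",
    "regression_stats",
    "r2_pred",
    "field_contributions",
    "scramble_validate",
    "contour_regions",
    "train_test_split_ids",
]


# ---------------------------------------------------------------------------
# core fitting

def _as_matrix(X) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(X, DescriptorMatrix):
        return X.values.to_numpy(dtype=float), X.columns
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), None
    return np.asarray(X, dtype=float), None


def fit_pls(X, y, n_components: int) -> PLSRegression:
    """Fit a centred (unscaled) PLS model; deterministic for fixed inputs."""
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if np.ptp(y) == 0:
        raise ValueError("constant activity vector: nothing to model")
    if not 1 <= n_components < X.shape[0]:
        raise ValueError("n_components must satisfy 1 <= c < n_train")
    if n_components > X.shape[1]:
        raise ValueError("n_components cannot exceed the number of descriptors")
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)
    return model


def _predict(model: PLSRegression, X) -> np.ndarray:
    X, _ = _as_matrix(X)
    return model.predict(X).ravel()


def loo_q2(X, y, n_components: int) -> float:
    """Leave-one-out ``q2 = 1 - PRESS/SS_tot`` (SS_tot about the full mean)."""
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 training molecules for LOO")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = fit_pls(X[mask], y[mask], n_components)
        press += float(m.predict(X[i : i + 1]).ravel()[0] - y[i]) ** 2
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


def select_optimal_components(X, y, max_components: int) -> tuple[int, dict[int, float]]:
    """Smallest component count attaining the maximal LOO q2 within the cap.

    Returns ``(n_opt, {c: q2})``.  Ties break toward the smaller count; the
    scan never exceeds ``n_train - 1`` components.
    """
    Xm, _ = _as_matrix(X)
    # each LOO fold fits on n-1 samples, so the scan stops at n-2 components
    hi = min(max_components, Xm.shape[0] - 2, Xm.shape[1])
    if hi < 1:
        raise ValueError("not enough training molecules")
    scores = {c: loo_q2(Xm, y, c) for c in range(1, hi + 1)}
    best = max(scores.values())
    n_opt = min(c for c, v in scores.items() if v == best)
    return n_opt, scores


def regression_stats(model: PLSRegression, X, y, q2: float | None = None) -> dict:
    """R2, SEE, F (and overfit ratio when q2 is given) for a fitted model."""
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    c = model.n_components
    n = len(y)
    dof = n - c - 1
    if dof <= 0:
        raise ValueError("n - c - 1 must be positive for SEE/F")
    resid = y - _predict(model, X)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    see = float(np.sqrt(ss_res / dof))
    f = (r2 / c) / ((1.0 - r2) / dof) if r2 < 1.0 else float("inf")
    out = {"r2": r2, "see": see, "f": f, "n_components": c, "n": n}
    if q2 is not None:
        out["overfit_pct"] = overfit_ratio(q2, r2)
    return out


def overfit_ratio(q2: float, r2: float) -> float:
    """(R2 - q2)/R2 as a percentage; the usual no-overfitting screen is < 25."""
    if r2 == 0:
        raise ValueError("R2 = 0: overfit ratio undefined")
    return 100.0 * (r2 - q2) / r2


def r2_pred(y_test, y_hat, train_mean: float) -> float:
    """External predictivity about the training mean; may be negative."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_test.size == 0:
        raise ValueError("need at least one test molecule")
    denom = float(((y_test - train_mean) ** 2).sum())
    if denom == 0:
        raise ValueError("test values all equal the training mean; r2_pred undefined")
    return 1.0 - float(((y_test - y_hat) ** 2).sum()) / denom


def field_contributions(model: PLSRegression, X, field_types: Sequence[str]) -> dict[str, float]:
    """Fraction of |coefficient| * column-std mass per field type (sums to 1)."""
    X, _ = _as_matrix(X)
    coef = np.asarray(model.coef_).ravel()
    std = X.std(axis=0, ddof=1)
    mass = np.abs(coef) * std
    types = np.asarray(field_types)
    total = mass.sum()
    out = {}
    for t in ("steric", "electrostatic"):
        out[t] = float(mass[types == t].sum() / total) if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# progressive scrambling

@dataclass(frozen=True)
class ScramblingReport:
    """Progressive y-scrambling summary.

    ``Q2`` and ``cSDEP`` are the quadratic fits of q2 and SDEP against the
    scrambled-to-original correlation r2yy', evaluated at the critical point
    (0.85 by convention); ``dq2_dr2yy`` is the fitted slope there.
    Methodology-compatible with, not bit-compatible to, the commercial
    implementation.
    """

    q2_scrambled: float
    csdep: float
    dq2_dr2yy: float
    critical_point: float
    levels: pd.DataFrame  # columns: r2yy, q2, sdep


def _partial_scramble(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Permute a random subset of k entries of y among themselves."""
    y = y.copy()
    if k >= 2:
        idx = rng.choice(len(y), size=k, replace=False)
        y[idx] = y[rng.permutation(idx)]
    return y


def scramble_validate(
    X,
    y,
    n_components: int,
    levels: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    reps: int = 3,
    seed: int = 0,
    critical_point: float = 0.85,
) -> ScramblingReport:
    """Progressive scrambling: perturb y in steps, track q2 vs r2yy'.

    ``levels`` are fractions of entries permuted (0 = intact response);
    each nonzero level is replicated ``reps`` times.  Deterministic for a
    fixed seed.
    """
    if len(levels) < 3:
        raise ValueError("need at least 3 scrambling levels for the quadratic fit")
    if reps < 2:
        raise ValueError("need reps >= 2 per scrambling level")
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in levels:
        k = int(round(frac * n))
        n_draws = 1 if k < 2 else reps
        for _ in range(n_draws):
            ys = _partial_scramble(y, k, rng)
            r = np.corrcoef(y, ys)[0, 1] if np.ptp(ys) > 0 else 0.0
            q2 = loo_q2(Xm, ys, n_components) if np.ptp(ys) > 0 else np.nan
            press = (1.0 - q2) * float(((ys - ys.mean()) ** 2).sum())
            rows.append({"r2yy": r * r, "q2": q2, "sdep": np.sqrt(max(press, 0.0) / n)})
    pts = pd.DataFrame(rows).dropna()
    t = pts["r2yy"].to_numpy()
    cq = np.polyfit(t, pts["q2"].to_numpy(), 2)
    cs = np.polyfit(t, pts["sdep"].to_numpy(), 2)
    tc = critical_point
    return ScramblingReport(
        q2_scrambled=float(np.polyval(cq, tc)),
        csdep=float(np.polyval(cs, tc)),
        dq2_dr2yy=float(2 * cq[0] * tc + cq[1]),
        critical_point=tc,
        levels=pts,
    )


# ---------------------------------------------------------------------------
# contours and splitting

_COLOR = {("steric", 1): "green", ("steric", -1): "yellow",
          ("electrostatic", 1): "blue", ("electrostatic", -1): "red"}
_GUIDE = {
    "green": "bulk here raises activity; small groups nearby reduce it",
    "yellow": "bulk here lowers activity; large groups nearby reduce it",
    "blue": "positive charge here raises activity; negative groups nearby reduce it",
    "red": "negative charge here raises activity; positive groups nearby reduce it",
}


def contour_regions(
    model: PLSRegression,
    X: DescriptorMatrix,
    support_frac: float = 0.8,
) -> pd.DataFrame:
    """Rank grid columns by |stdev * coefficient| and label contour classes.

    The top ``support_frac`` of the stdev*coeff mass is flagged ``support``
    (the regions drawn on a contour map); the remainder is non-support.
    Colors follow the CoMFA reading: green/yellow for favorable/unfavorable
    steric bulk, blue/red for favorable positive/negative charge — each with
    a plain-text modification hint for activity *reduction*.
    """
    if not 0 <= support_frac <= 1:
        raise ValueError("support_frac must lie in [0, 1]")
    coef = np.asarray(model.coef_).ravel()
    std = X.values.std(axis=0, ddof=1).to_numpy()
    score = std * coef
    out = X.columns.copy()
    out["stdev_coeff"] = score
    order = np.argsort(-np.abs(score), kind="stable")
    mass = np.abs(score)[order]
    total = mass.sum()
    cum = np.cumsum(mass)
    # a column is supportive while the mass accumulated *before* it is < frac
    support_sorted = (cum - mass) < support_frac * total if total > 0 else mass > 0
    support = np.empty_like(support_sorted)
    support[order] = support_sorted
    out["support"] = support
    sign = np.where(score >= 0, 1, -1)
    out["color"] = [_COLOR[(f, s)] for f, s in zip(out["field"], sign)]
    out["guidance"] = out["color"].map(_GUIDE)
    return out.sort_values("stdev_coeff", key=np.abs, ascending=False)


def train_test_split_ids(ids: Sequence, n_test: int, seed: int) -> tuple[list, list]:
    """Seeded random train/test split of molecule ids (template stays put)."""
    ids = list(ids)
    if not 0 < n_test < len(ids):
        raise ValueError("n_test must be in (0, n_molecules)")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(len(ids), size=n_test, replace=False).tolist())
    train = [m for i, m in enumerate(ids) if i not in test_idx]
    test = [m for i, m in enumerate(ids) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# model facade

class ComfaPLS:
    """Field-descriptor PLS model of an activity.

    Parameters
    ----------
    X
        :class:`~qsarmix.fields.DescriptorMatrix` (preferred; carries field
        types and grid coordinates) or a plain 2-D array/DataFrame.
    y
        Activity vector aligned with the rows of ``X``.
    min_sigma
        Columns with std below this (kcal/mol) are dropped before fitting
        and recorded on the descriptor matrix (2.0 is the CoMFA default).
    """

    def __init__(self, X, y, min_sigma: float = 2.0):
        y = np.asarray(y, dtype=float).ravel()
        if isinstance(X, DescriptorMatrix):
            X = X.filtered(min_sigma)
            if X.values.shape[1] == 0:
                raise ValueError(
                    "column filter removed every descriptor "
                    f"(min_sigma={min_sigma}); no variance to model"
                )
            self.descriptor = X
            self.exog = X.values.to_numpy(dtype=float)
            self.field_types = X.field_types
        else:
            Xm, _ = _as_matrix(X)
            self.descriptor = None
            self.exog = Xm
            self.field_types = np.array(["steric"] * Xm.shape[1])
        if self.exog.shape[0] != y.shape[0]:
            raise ValueError("X rows and y length differ")
        self.endog = y
        self.min_sigma = min_sigma

    def fit(self, n_components: int | None = None, max_components: int = 6) -> "ComfaResults":
        """Fit the PLS model; pick ``n_components`` by LOO q2 when omitted."""
        if n_components is None:
            n_components, scan = select_optimal_components(
                self.exog, self.endog, max_components
            )
            q2 = scan[n_components]
        else:
            scan = None
            q2 = loo_q2(self.exog, self.endog, n_components)
        model = fit_pls(self.exog, self.endog, n_components)
        stats = regression_stats(model, self.exog, self.endog, q2=q2)
        contrib = field_contributions(model, self.exog, self.field_types)
        return ComfaResults(
            model=self, pls=model, n_components=n_components, q2=q2,
            r2=stats["r2"], see=stats["see"], f_stat=stats["f"],
            overfit_pct=stats["overfit_pct"], contributions=contrib,
            component_scan=scan,
        )


@dataclass
class ComfaResults:
    """Fitted CoMFA/PLS model with its internal-validation statistics."""

    model: ComfaPLS
    pls: PLSRegression
    n_components: int
    q2: float
    r2: float
    see: float
    f_stat: float
    overfit_pct: float
    contributions: dict
    component_scan: dict | None = None
    _scrambling: ScramblingReport | None = field(default=None, repr=False)

    @property
    def coef(self) -> np.ndarray:
        return np.asarray(self.pls.coef_).ravel()

    def predict(self, X) -> np.ndarray:
        if isinstance(X, DescriptorMatrix) and self.model.descriptor is not None:
            X = X.values.loc[:, self.model.descriptor.values.columns]
        return _predict(self.pls, X)

    def external_validation(self, X_test, y_test) -> float:
        """r2_pred of held-out molecules about this model's training mean."""
        return r2_pred(y_test, self.predict(X_test), float(self.model.endog.mean()))

    def scramble(self, seed: int = 0, **kw) -> ScramblingReport:
        self._scrambling = scramble_validate(
            self.model.exog, self.model.endog, self.n_components, seed=seed, **kw
        )
        return self._scrambling

    def contour_regions(self, support_frac: float = 0.8) -> pd.DataFrame:
        if self.model.descriptor is None:
            raise ValueError("contour regions need a DescriptorMatrix-backed model")
        return contour_regions(self.pls, self.model.descriptor, support_frac)

    def summary(self) -> str:
        buf = io.StringIO()
        n = len(self.model.endog)
        p = self.model.exog.shape[1]
        w = buf.write
        w("Field-PLS QSAR results\n")
        w("=" * 46 + "\n")
        w(f"molecules: {n}   descriptors kept: {p}")
        if self.model.descriptor is not None:
            w(f"   dropped: {len(self.model.descriptor.dropped)}")
        w("\n\n")
        rows = [
            ("q2 (LOO)", f"{self.q2:.3f}"),
            ("n components", f"{self.n_components}"),
            ("R2", f"{self.r2:.3f}"),
            ("SEE", f"{self.see:.3f}"),
            ("F", f"{self.f_stat:.3f}"),
            ("(R2-q2)/R2 %", f"{self.overfit_pct:.3f}"),
            ("steric contribution", f"{100 * self.contributions['steric']:.1f}%"),
            ("electrostatic contribution",
             f"{100 * self.contributions['electrostatic']:.1f}%"),
        ]
        if self._scrambling is not None:
            s = self._scrambling
            rows += [("scrambling Q2", f"{s.q2_scrambled:.3f}"),
                     ("cSDEP", f"{s.csdep:.3f}"),
                     ("dq2/dr2yy'", f"{s.dq2_dr2yy:.3f}")]
        for k, v in rows:
            w(f"{k:<28}{v:>12}\n")
        return buf.getvalue()
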