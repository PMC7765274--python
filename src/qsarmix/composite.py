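"""Coefficient-of-variation weighting of multi-endpoint docking scores.

Several docking endpoints (one per receptor enzyme) produce one score column
each.  The endpoints are fused into a single comprehensive biotoxicity index
(CI) per molecule by weighting each endpoint with its coefficient of
variation: endpoints that discriminate more between molecules (larger CV)
receive proportionally more weight.  For endpoint ``j`` over ``n`` molecules

    mean_j = (1/n) sum_i X_ij
    std_j  = sqrt((1/n) sum_i (X_ij - mean_j)^2)      (population form)
    cv_j   = std_j / mean_j
    w_j    = cv_j / sum_k cv_k

and per molecule ``i`` the individual index and composite index are

    H_ij = X_ij / mean_j,        CI_i = sum_j H_ij * w_j .

A molecule scoring exactly at every column mean therefore has CI = 1; CI is
invariant to rescaling any single endpoint column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EndpointScoreTable",
    "VariationWeights",
    "CompositeIndexTable",
    "CompositeIndexModel",
    "CompositeIndexResults",
    "compute_variation_weights",
    "compute_composite_index",
]


@dataclass(frozen=True)
class EndpointScoreTable:
    """Molecules x endpoints docking-score matrix.

    Parameters
    ----------
    scores
        DataFrame indexed by molecule id with one column per endpoint.
        All entries must be finite; missing scores are rejected (the
        weighting has no imputation semantics).
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.scores
        if df.shape[0] < 2:
            raise ValueError("need at least 2 molecules")
        if df.shape[1] < 1:
            raise ValueError("need at least 1 endpoint")
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("molecule and endpoint ids must be unique")
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"missing scores for molecules {bad}; drop or supply them")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")

    @property
    def molecule_ids(self) -> list:
        return list(self.scores.index)

    @property
    def endpoint_ids(self) -> list:
        return list(self.scores.columns)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "EndpointScoreTable":
        """Read a header table: first column molecule id, then endpoints."""
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        return cls(df.astype(float))


@dataclass(frozen=True)
class VariationWeights:
    """Per-endpoint mean, population std, CV and normalized weight."""

    endpoint_ids: tuple
    mean: np.ndarray
    std: np.ndarray
    cv: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if not abs(self.weight.sum() - 1.0) < 1e-12:
            raise ValueError("weights must sum to 1")
        if (self.std < 0).any() or (self.cv < 0).any() or (self.weight < 0).any():
            raise ValueError("std, cv and weights must be nonnegative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "std": self.std, "cv": self.cv, "weight": self.weight},
            index=list(self.endpoint_ids),
        )


@dataclass(frozen=True)
class CompositeIndexTable:
    """Individual indices H_ij and composite index CI_i, molecule-ordered."""

    individual: pd.DataFrame
    ci: pd.Series

    def as_frame(self, decimals: int | None = None) -> pd.DataFrame:
        out = self.individual.add_prefix("H_").copy()
        out["CI"] = self.ci
        return out.round(decimals) if decimals is not None else out


def compute_variation_weights(scores: EndpointScoreTable) -> VariationWeights:
    """CV weights from a score table (population std, divisor ``n``).

    Raises
    ------
    ValueError
        ``"cv undefined"`` if any column mean is zero; ``"degenerate
        weights"`` if every column is constant (all CVs zero).
    """
    X = scores.values
    mean = X.mean(axis=0)
    if np.any(mean == 0):
        raise ValueError("cv undefined: zero column mean")
    std = X.std(axis=0, ddof=0)
    cv = std / np.abs(mean)
    total = cv.sum()
    if total == 0:
        raise ValueError("degenerate weights: all endpoint columns constant")
    return VariationWeights(
        endpoint_ids=tuple(scores.endpoint_ids),
        mean=mean, std=std, cv=cv, weight=cv / total,
    )


def compute_composite_index(
    scores: EndpointScoreTable,
    weights: VariationWeights | None = None,
    denominator: str | Sequence[float] = "mean",
) -> CompositeIndexTable:
    """Composite index CI_i = sum_j (X_ij / mean_j) * w_j.

    Parameters
    ----------
    weights
        Precomputed :class:`VariationWeights`; computed from ``scores`` when
        omitted.  Endpoint ids must match the table.
    denominator
        Normalizer for the individual indices H_ij.  ``"mean"`` (default)
        uses the column means; a sequence of per-endpoint reference values
        may be supplied instead for sensitivity checks.
    """
    if weights is None:
        weights = compute_variation_weights(scores)
    if tuple(scores.endpoint_ids) != tuple(weights.endpoint_ids):
        raise ValueError(
            f"endpoint mismatch: table has {scores.endpoint_ids}, "
            f"weights cover {list(weights.endpoint_ids)}"
        )
    if isinstance(denominator, str):
        if denominator != "mean":
            raise ValueError(f"unknown denominator strategy {denominator!r}")
        denom = weights.mean
    else:
        denom = np.asarray(denominator, dtype=float)
        if denom.shape != (len(weights.endpoint_ids),):
            raise ValueError("denominator length must match endpoint count")
        if np.any(denom == 0):
            raise ValueError("denominator values must be nonzero")
    H = scores.scores / denom
    ci = H.mul(weights.weight, axis=1).sum(axis=1)
    ci.name = "CI"
    return CompositeIndexTable(individual=H, ci=ci)


class CompositeIndexModel:
    """Model-style wrapper: score table in, fitted weights + CI table out.

    Examples
    --------
    >>> res = CompositeIndexModel(table).fit()
    >>> res.ci["ENR"]            # doctest: +SKIP
    >>> print(res.summary())     # doctest: +SKIP
    """

    def __init__(self, scores: EndpointScoreTable | pd.DataFrame):
        if isinstance(scores, pd.DataFrame):
            scores = EndpointScoreTable(scores)
        self.scores = scores

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "CompositeIndexModel":
        return cls(EndpointScoreTable.from_csv(path, sep=sep))

    def fit(self, denominator: str | Sequence[float] = "mean") -> "CompositeIndexResults":
        weights = compute_variation_weights(self.scores)
        table = compute_composite_index(self.scores, weights, denominator=denominator)
        return CompositeIndexResults(self, weights, table)


@dataclass(frozen=True)
class CompositeIndexResults:
    model: CompositeIndexModel
    weights: VariationWeights
    table: CompositeIndexTable

    @property
    def ci(self) -> pd.Series:
        return self.table.ci

    def summary(self, decimals: int = 3) -> str:
        w = self.weights.as_frame().round(4)
        t = self.table.as_frame(decimals=decimals)
        lines = [
            "Composite biotoxicity index (CV weighting)",
            "=" * 44,
            f"molecules: {len(self.model.scores.molecule_ids)}   "
            f"endpoints: {len(self.weights.endpoint_ids)}",
            "",
            "Endpoint weights:",
            w.to_string(),
            "",
            f"Composite index (rounded to {decimals} dp):",
            t.to_string(),
        ]
        return "\n".join(lines)
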