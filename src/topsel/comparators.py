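"""Classical multi-trait selection schemes used as benchmarks: independent
culling levels and the desired-gains (Pesek-Baker) selection index, plus the
shared 0.5-SD success metric.

The index weight vector solves b = P^-1 G* [G*' P^-1 G*]^-1 Q, where P and G
are the phenotypic and additive-genetic variance-covariance matrices, Q the
vector of desired gains on a trait subset, and G* the columns of G for those
traits; the implied Smith-Hazel economic values are a = G^-1 P b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndexSpec",
    "culling_select",
    "desired_gains_weights",
    "economic_values",
    "index_select",
    "selection_success_rate",
]

logger = logging.getLogger(__name__)


def _as_frame(phenotypes, ids=None) -> pd.DataFrame:
    if isinstance(phenotypes, pd.DataFrame):
        return phenotypes
    X = np.asarray(phenotypes, float)
    idx = ids if ids is not None else [f"{i:06d}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=[str(i) for i in idx])


@dataclass
class IndexSpec:
    """A desired-gains index problem and its solution."""

    trait_names: list[str]
    P: np.ndarray
    G: np.ndarray
    Q: np.ndarray
    q_traits: list[str]
    b: np.ndarray
    a: np.ndarray

    @classmethod
    def build(cls, trait_names, P, G, Q, q_traits) -> "IndexSpec":
        b = desired_gains_weights(P, G, Q, [trait_names.index(t) for t in q_traits])
        a = economic_values(P, G, b)
        return cls(list(trait_names), np.asarray(P, float), np.asarray(G, float),
                   np.asarray(Q, float), list(q_traits), b, a)


def culling_select(phenotypes, directions: dict, top_n: int, ids=None) -> list[str]:
    """Independent culling levels: per trait keep the ``top_n`` candidates in
    the favourable direction, then intersect across traits.

    The intersection may be empty when traits are antagonistic; that is a
    legitimate outcome of the method and is logged, not raised.
    """
    df = _as_frame(phenotypes, ids)
    if top_n > len(df) or top_n < 1:
        raise ValueError("top_n must lie in [1, N]")
    kept: set | None = None
    for trait, direction in directions.items():
        col = df[trait]
        ascending = direction == "low"
        order = col.sort_values(ascending=ascending, kind="mergesort")
        chosen = set(order.index[:top_n])
        kept = chosen if kept is None else kept & chosen
    if kept is None:
        raise ValueError("no trait directions given")
    if not kept:
        logger.info("culling intersection is empty for directions %s", directions)
    return sorted(kept)


def desired_gains_weights(P, G, Q, q_trait_indices) -> np.ndarray:
    """Index weights b = P^-1 G* [G*' P^-1 G*]^-1 Q.

    ``q_trait_indices`` selects the columns of G corresponding to the traits
    with specified desired gains; the defining identity G*' b = Q holds at
    the solution to numerical precision.
    """
    P = np.asarray(P, float)
    G = np.asarray(G, float)
    Q = np.asarray(Q, float).ravel()
    d = P.shape[0]
    if P.shape != (d, d) or G.shape != (d, d):
        raise ValueError("P and G must be square and conformable")
    idx = list(q_trait_indices)
    if len(idx) != Q.size or len(idx) >= d + 1:
        raise ValueError("Q length must match its trait subset")
    Gs = G[:, idx]
    try:
        PinvGs = np.linalg.solve(P, Gs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phenotypic covariance P is singular") from exc
    M = Gs.T @ PinvGs
    try:
        lam = np.linalg.solve(M, Q)
    except np.linalg.LinAlgError as exc:
        raise ValueError("G*' P^-1 G* is singular") from exc
    return PinvGs @ lam


def economic_values(P, G, b) -> np.ndarray:
    """Implied Smith-Hazel economic values a = G^-1 P b."""
    G = np.asarray(G, float)
    P = np.asarray(P, float)
    b = np.asarray(b, float).ravel()
    try:
        return np.linalg.solve(G, P @ b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("genetic covariance G is singular") from exc


def index_select(b, phenotypes, top_n: int, ids=None) -> list[str]:
    """Rank candidates by the linear index I = b'x and return the top n.

    Ties are broken by candidate id, so selection is deterministic.
    """
    df = _as_frame(phenotypes, ids)
    b = np.asarray(b, float).ravel()
    if b.size != df.shape[1]:
        raise ValueError("index weight length mismatch")
    scores = df.to_numpy(float) @ b
    order = sorted(range(len(df)), key=lambda i: (-scores[i], str(df.index[i])))
    return [str(df.index[i]) for i in order[:top_n]]


def selection_success_rate(
    selected_values,
    method: str,
    directions: dict | None = None,
    reference_mean=None,
    reference_sd=None,
    target_values=None,
    per_trait: bool = False,
):
    """Fraction of selected candidates that satisfy the 0.5-SD success rule.

    Truncation-style methods (``method='culling'`` or ``'index'``): a
    candidate succeeds on a trait when its observed value is strictly beyond
    the testing-population mean by 0.5 SD in the favourable direction.
    Similarity-style selection (``method='top'``): success on a trait means
    the observed value is strictly within 0.5 SD of the target's value.
    A candidate counts as an overall success only if every considered trait
    succeeds; the per-trait rates are available via ``per_trait=True``.
    """
    df = selected_values if isinstance(selected_values, pd.DataFrame) else pd.DataFrame(
        np.atleast_2d(np.asarray(selected_values, float))
    )
    if len(df) == 0:
        raise ValueError("no selected candidates")
    sd = pd.Series(reference_sd, index=df.columns) if not np.isscalar(reference_sd) else pd.Series(
        float(reference_sd), index=df.columns
    )
    if method in ("culling", "index", "culling_or_index"):
        if directions is None or reference_mean is None:
            raise ValueError("culling/index success needs directions and reference_mean")
        mean = pd.Series(reference_mean, index=df.columns) if not np.isscalar(
            reference_mean
        ) else pd.Series(float(reference_mean), index=df.columns)
        ok = {}
        for trait, direction in directions.items():
            thresh = mean[trait] + 0.5 * sd[trait]
            low = mean[trait] - 0.5 * sd[trait]
            ok[trait] = df[trait] > thresh if direction == "high" else df[trait] < low
        ok = pd.DataFrame(ok)
    elif method == "top":
        if target_values is None:
            raise ValueError("top success needs target_values")
        target = pd.Series(target_values, index=df.columns) if not np.isscalar(
            target_values
        ) else pd.Series(float(target_values), index=df.columns)
        traits = list(directions) if directions else list(df.columns)
        ok = pd.DataFrame(
            {t: (df[t] - target[t]).abs() < 0.5 * sd[t] for t in traits}
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    rate = float(ok.all(axis=1).mean())
    if per_trait:
        return rate, ok.mean(axis=0)
    return rate
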