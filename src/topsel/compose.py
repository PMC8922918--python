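"""Composing omics feature layers into principal-component traits and
filtering traits by prediction accuracy or learned weight.

High-dimensional transcriptomic / metabolic layers are reduced per layer to
the smallest set of principal components reaching a cumulative explained
variance target (default 80%); component scores then enter the toolkit as
ordinary traits.  Two filters clean the trait set around weight learning:
drop traits whose genomic prediction accuracy is poor (they inject noise into
the similarity), and drop traits whose learned weight comes out negative
(the model is then retrained on the survivors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import PredictionSet, TraitWeights

__all__ = ["ComposedTraits", "compose_pcs", "filter_by_accuracy", "filter_by_weight"]


@dataclass
class ComposedTraits:
    """Principal-component trait scores for one omics layer."""

    individual_ids: list[str]
    scores: np.ndarray  # n x q, centered
    explained_variance_fractions: np.ndarray  # length q
    loadings: np.ndarray  # f x q
    var_target: float

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_dataframe(self, prefix: str = "PC") -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.individual_ids,
            columns=[f"{prefix}{k + 1}" for k in range(self.n_components)],
        )


def compose_pcs(features, var_target: float = 0.8, standardize: bool = True) -> ComposedTraits:
    """Reduce one omics layer to PCs covering ``var_target`` of the variance.

    Features are standardized to unit variance by default (expression and
    metabolite intensities live on incommensurate scales); ``q`` is the
    smallest component count whose cumulative explained-variance fraction
    reaches the target.
    """
    if not 0.0 < var_target <= 1.0:
        raise ValueError("var_target must lie in (0, 1]")
    if isinstance(features, pd.DataFrame):
        ids = [str(i) for i in features.index]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 individuals for PCA")
    if np.isnan(X).all(axis=0).any():
        raise ValueError("feature with no observed values")
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means[None, :], X)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=min(X.shape) if X.shape[0] > X.shape[1] else None)
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    q = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    q = min(q, frac.size)
    return ComposedTraits(
        ids, scores[:, :q], frac[:q], pca.components_[:q].T, var_target
    )


def filter_by_accuracy(prediction_set_or_accuracies, r_min: float) -> list[str]:
    """Retain traits whose genomic prediction accuracy is at least ``r_min``.

    Exclusion is strict (r < r_min removed, boundary kept); order preserved.
    """
    if isinstance(prediction_set_or_accuracies, PredictionSet):
        names = list(prediction_set_or_accuracies.trait_names)
        acc = prediction_set_or_accuracies.accuracies()
    else:
        series = pd.Series(prediction_set_or_accuracies)
        names, acc = [str(i) for i in series.index], series.to_numpy(float)
    kept = [t for t, r in zip(names, acc) if r >= r_min]
    if not kept:
        raise ValueError(
            f"no trait reaches prediction accuracy {r_min}; relax the threshold"
        )
    return kept


def filter_by_weight(weights: TraitWeights) -> list[str]:
    """Retain traits with non-negative learned weight (w < 0 removed).

    The caller is expected to re-learn weights on the surviving traits.
    """
    kept = [t for t, w in zip(weights.trait_names, weights.w) if w >= 0]
    if not kept:
        warnings.warn("all trait weights are negative; returning empty trait list")
    return kept
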