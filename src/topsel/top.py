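"""Target-oriented prioritization: softmax similarity over weighted L1
distances, maximum-likelihood trait-weight learning, and candidate ranking.

The similarity of a target profile Y to candidate n with predicted profile
Yhat^n is the softmax of the negative weighted L1 distance

    P(Y, Yhat^n) = exp(-sum_i w_i |Y_i - Yhat_i^n|) / sum_m exp(-D_m),

normalised over the candidate pool.  Trait weights w are learned on a
training population with paired observed/predicted values by maximising the
self-identification likelihood L(w) = prod_n P(Y^n, Yhat^n): each training
individual's observed profile should pick out its own prediction among all
candidates.  Optimisation starts from w = 1 (all traits equal) and uses the
quasi-Newton method in :mod:`topsel.optimize`; weights are unconstrained, and
traits that come out negative are usually dropped and the model retrained
(see :mod:`topsel.compose`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import PredictionSet, SelectionResult, TraitWeights
from .optimize import bfgs_minimize

__all__ = [
    "weighted_l1_distance",
    "pairwise_weighted_l1",
    "similarity_scores",
    "top_negative_log_likelihood",
    "learn_weights",
    "rank_candidates",
    "TOPModel",
    "TOPResults",
]


def _weights_vector(w, d: int) -> np.ndarray:
    if isinstance(w, TraitWeights):
        w = w.w
    w = np.asarray(w, dtype=float).ravel()
    if w.size != d:
        raise ValueError(f"weight length {w.size} != trait count {d}")
    return w


def weighted_l1_distance(y, yhat, w) -> float:
    """Sum_i w_i |y_i - yhat_i| between two trait profiles."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size != yhat.size:
        raise ValueError("profile length mismatch")
    return float(_weights_vector(w, y.size) @ np.abs(y - yhat))


def pairwise_weighted_l1(targets, candidates, w) -> np.ndarray:
    """(n_targets, n_candidates) matrix of weighted L1 distances."""
    T = np.atleast_2d(np.asarray(targets, float))
    C = np.atleast_2d(np.asarray(candidates, float))
    wv = _weights_vector(w, T.shape[1])
    return np.einsum("tcd,d->tc", np.abs(T[:, None, :] - C[None, :, :]), wv)


def similarity_scores(target, predictions, w) -> np.ndarray:
    """Softmax similarity of one target profile to each candidate prediction.

    Computed with max-subtraction so large distances cannot overflow; scores
    are positive and sum to one over the pool.
    """
    predictions = np.atleast_2d(np.asarray(predictions, float))
    target = np.asarray(target, float).ravel()
    if not (np.isfinite(target).all() and np.isfinite(predictions).all()):
        raise ValueError("non-finite inputs")
    D = pairwise_weighted_l1(target[None, :], predictions, w)[0]
    z = -D
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def top_negative_log_likelihood(w, prediction_set, return_probs: bool = False):
    """Negative log self-identification likelihood and its analytic gradient.

    For each training individual n, the probability that its observed profile
    Y^n selects its own prediction among all N candidate predictions is the
    softmax p_nn over distances D(Y^n, Yhat^m; w).  The value is
    -sum_n log p_nn and the gradient component for trait j is

        sum_n ( |Y_j^n - Yhat_j^n| - sum_m p_nm |Y_j^n - Yhat_j^m| ).
    """
    if isinstance(prediction_set, PredictionSet):
        Y, Yhat = prediction_set.observed, prediction_set.predicted
    else:
        Y, Yhat = prediction_set
        Y = np.asarray(Y, float)
        Yhat = np.asarray(Yhat, float)
    N, d = Y.shape
    if N < 2:
        raise ValueError("likelihood degenerate with fewer than 2 individuals")
    wv = _weights_vector(w, d)
    A = np.abs(Y[:, None, :] - Yhat[None, :, :])  # (N, N, d)
    D = A @ wv
    lse = logsumexp(-D, axis=1)
    value = float(np.sum(lse + np.diagonal(D)))
    P = np.exp(-D - lse[:, None])  # softmax rows
    diag_idx = np.arange(N)
    grad = A[diag_idx, diag_idx, :].sum(axis=0) - np.einsum("nm,nmd->d", P, A)
    if return_probs:
        return value, grad, P
    return value, grad


class _NLL:
    """Caches the |Y - Yhat| tensor so each optimiser step is one einsum."""

    def __init__(self, Y, Yhat):
        self.A = np.abs(Y[:, None, :] - Yhat[None, :, :])
        self.diag = self.A[np.arange(Y.shape[0]), np.arange(Y.shape[0]), :]

    def __call__(self, w):
        D = self.A @ w
        lse = logsumexp(-D, axis=1)
        value = float(np.sum(lse + np.diagonal(D)))
        P = np.exp(-D - lse[:, None])
        grad = self.diag.sum(axis=0) - np.einsum("nm,nmd->d", P, self.A)
        return value, grad


class TOPModel:
    """Trait-weight learner for target-oriented prioritization.

    Parameters
    ----------
    prediction_set : PredictionSet with paired observed/predicted trait
        values for the training population (typically produced by
        :func:`topsel.gblup.kfold_self_predictions`).
    standardize : z-scale each trait (observed SD) before computing
        distances.  Off by default — the weights absorb trait scale — but
        useful for numerical conditioning with wildly different units.
    """

    def __init__(self, prediction_set: PredictionSet, standardize: bool = False):
        self.prediction_set = prediction_set
        self.standardize = standardize
        self.trait_names = list(prediction_set.trait_names)
        Y = prediction_set.observed
        Yhat = prediction_set.predicted
        if standardize:
            sd = Y.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError("constant trait cannot be standardized")
            self._scale = sd
            Y = Y / sd
            Yhat = Yhat / sd
        else:
            self._scale = np.ones(Y.shape[1])
        self._Y, self._Yhat = Y, Yhat
        self._nll = _NLL(Y, Yhat)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def nloglike(self, w):
        return self._nll(np.asarray(w, float))

    def fit(
        self, start=None, grad_tol: float = 1e-6, max_iter: int = 500
    ) -> "TOPResults":
        """Learn weights by quasi-Newton maximum likelihood from w = 1."""
        x0 = np.ones(self.n_traits) if start is None else np.asarray(start, float)
        res = bfgs_minimize(self._nll, x0, grad_tol=grad_tol, max_iter=max_iter)
        weights = TraitWeights(
            list(self.trait_names),
            res.x / self._scale,  # back on the raw-trait scale
            converged=res.converged,
            grad_norm=res.grad_norm,
            n_iter=res.n_iter,
        )
        return TOPResults(self, weights, res)


class TOPResults:
    """Learned trait weights plus diagnostics and ranking methods."""

    def __init__(self, model: TOPModel, weights: TraitWeights, optimize_result):
        self.model = model
        self.weights = weights
        self.optimize_result = optimize_result

    @property
    def params(self) -> np.ndarray:
        return self.weights.w

    @property
    def nll(self) -> float:
        return self.optimize_result.fval

    @property
    def converged(self) -> bool:
        return self.weights.converged

    def rank(self, target, candidate_predictions, candidate_ids, label="target"):
        return rank_candidates(
            target, candidate_predictions, self.weights, candidate_ids, label=label
        )

    def summary(self) -> str:
        ps = self.model.prediction_set
        df = pd.DataFrame(
            {
                "trait": self.weights.trait_names,
                "weight": self.weights.w,
                "accuracy_r": ps.accuracies(),
            }
        )
        lines = [
            "Target-oriented prioritization (softmax similarity, weighted L1)",
            f"training individuals: {ps.n_individuals}   traits: {ps.n_traits}",
            f"neg. log-likelihood: {self.nll:.6f}   "
            f"converged: {self.converged} ({self.weights.n_iter} iterations, "
            f"||g|| = {self.weights.grad_norm:.2e})",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def learn_weights(
    prediction_set: PredictionSet,
    start=None,
    grad_tol: float = 1e-6,
    max_iter: int = 500,
    standardize: bool = False,
) -> TraitWeights:
    """Functional wrapper: fit a :class:`TOPModel` and return its weights."""
    return TOPModel(prediction_set, standardize=standardize).fit(
        start=start, grad_tol=grad_tol, max_iter=max_iter
    ).weights


def rank_candidates(
    target, candidate_predictions, w, candidate_ids, label="target"
) -> SelectionResult:
    """Order candidates by descending softmax similarity to a target profile.

    Ties (exact score equality) are broken by candidate id, lexicographically,
    so rankings are deterministic.
    """
    candidate_predictions = np.atleast_2d(np.asarray(candidate_predictions, float))
    target = np.asarray(target, float).ravel()
    if candidate_predictions.shape[1] != target.size:
        raise ValueError("target/candidate trait dimension mismatch")
    if len(candidate_ids) != candidate_predictions.shape[0]:
        raise ValueError("candidate id count mismatch")
    scores = similarity_scores(target, candidate_predictions, w)
    ids = [str(c) for c in candidate_ids]
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    trait_names = w.trait_names if isinstance(w, TraitWeights) else []
    return SelectionResult(
        target_label=str(label),
        candidate_ids=[ids[i] for i in order],
        scores=scores[order],
        trait_names=list(trait_names),
    )
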