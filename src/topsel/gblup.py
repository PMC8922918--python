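"""Single-trait GBLUP: kinship, REML variance components and BLUP prediction.

The mixed model is y = Xb + mu + e with mu ~ N(0, K sigma_g^2) and
e ~ N(0, I sigma_e^2); K is the centered-crossproduct genomic relationship
matrix.  Variance components are estimated by restricted maximum likelihood,
profiled over the heritability ratio h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)
after a single eigendecomposition of K, so repeated fits against the same
kinship (different traits, simulation replicates) cost one rotation each.

Genetic values of unphenotyped individuals follow from the BLUP equation
mu = sigma_g^2 K_{new,train} V^{-1} (y - Xb) with V = K sigma_g^2
+ I sigma_e^2 built on the training block; with K = I this reduces to the
scalar ridge shrinkage mu_i = h2 (y_i - ybar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import GenotypeMatrix, PhenotypeTable, PredictionSet

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "compute_kinship",
    "centered_dosages",
    "cross_kinship",
    "GBLUP",
    "GBLUPResults",
    "reml_fit",
    "gblup_predict",
    "kfold_self_predictions",
    "prediction_accuracy",
]


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix over a set of individuals."""

    individual_ids: list[str]
    K: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.individual_ids)
        if self.K.shape != (n, n):
            raise ValueError("K must be square over the individual ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def submatrix(self, ids) -> "KinshipMatrix":
        pos = {v: i for i, v in enumerate(self.individual_ids)}
        idx = [pos[i] for i in ids]
        return KinshipMatrix(list(ids), self.K[np.ix_(idx, idx)])


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    beta: np.ndarray  # fixed effects
    loglike: float  # restricted log-likelihood at the optimum

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components out of range")


def centered_dosages(dosages: np.ndarray, drop_monomorphic: bool = True):
    """Column-center a dosage matrix, optionally dropping monomorphic markers.

    Returns (centered matrix, boolean keep-mask over original columns).
    """
    dosages = np.asarray(dosages, dtype=float)
    keep = dosages.std(axis=0) > 0 if drop_monomorphic else np.ones(
        dosages.shape[1], dtype=bool
    )
    if not keep.any():
        raise ValueError("all markers are monomorphic")
    W = dosages[:, keep]
    return W - W.mean(axis=0), keep


def compute_kinship(genotypes: GenotypeMatrix | np.ndarray) -> KinshipMatrix:
    """Centered-crossproduct kinship K = Wc Wc' / m over polymorphic markers."""
    if isinstance(genotypes, GenotypeMatrix):
        ids, dosages = genotypes.individual_ids, genotypes.dosages
    else:
        dosages = np.asarray(genotypes, dtype=float)
        ids = [str(i) for i in range(dosages.shape[0])]
    Wc, keep = centered_dosages(dosages)
    K = Wc @ Wc.T / keep.sum()
    return KinshipMatrix(list(ids), K)


def cross_kinship(dosages: np.ndarray, row_idx, col_idx) -> np.ndarray:
    """Kinship block K[rows, cols] without materialising the full n x n matrix.

    Centering uses the marker means over *all* individuals in ``dosages`` so
    blocks are consistent with :func:`compute_kinship` on the full set.
    """
    Wc, keep = centered_dosages(dosages)
    return Wc[row_idx] @ Wc[col_idx].T / keep.sum()


def _as_eig(K, n):
    """Accept a KinshipMatrix, ndarray or precomputed (eigvals, eigvecs)."""
    if isinstance(K, tuple):
        lam, U = K
        return np.asarray(lam, float), np.asarray(U, float)
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    if Kmat.shape != (n, n):
        raise ValueError("kinship dimension does not match phenotypes")
    lam, U = np.linalg.eigh(Kmat)
    return np.clip(lam, 0.0, None), U


def reml_fit(y, K, X=None, h2_tol: float = 1e-8) -> VarianceComponents:
    """Restricted-ML variance components via a profile likelihood over h2.

    With K = U diag(lam) U', V = sigma_p^2 (h2 K + (1-h2) I) rotates to a
    diagonal GLS problem; the restricted likelihood is maximised over h2 in
    (1e-6, 1 - 1e-6) by bounded Brent search, with sigma_p^2 profiled out
    analytically.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector must be complete")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design must have full column rank")

    lam, U = _as_eig(K, n)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(h2: float) -> float:
        d = h2 * lam + (1.0 - h2)
        XtD = Xt / d[:, None]
        XtDX = Xt.T @ XtD
        beta = np.linalg.solve(XtDX, XtD.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / d))
        if rss <= 0 or not np.isfinite(rss):
            return np.inf
        sigma_p2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(sigma_p2)
            + np.sum(np.log(d))
            + np.linalg.slogdet(XtDX)[1]
            + (n - p)
        )
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite restricted likelihood")
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(1e-6, 1.0 - 1e-6),
        method="bounded",
        options={"xatol": h2_tol},
    )
    h2 = float(res.x)
    d = h2 * lam + (1.0 - h2)
    XtD = Xt / d[:, None]
    beta = np.linalg.solve(Xt.T @ XtD, XtD.T @ yt)
    r = yt - Xt @ beta
    sigma_p2 = float(r @ (r / d)) / (n - p)
    return VarianceComponents(
        sigma_g2=h2 * sigma_p2,
        sigma_e2=max((1.0 - h2) * sigma_p2, np.finfo(float).tiny),
        h2=h2,
        beta=beta,
        loglike=-float(res.fun),
    )


def gblup_predict(y, K_train, vc: VarianceComponents, X=None, K_cross=None, X_new=None):
    """BLUP genetic values (and predicted phenotypes) from a fitted model.

    ``K_cross`` holds kinship rows linking the individuals to predict with
    the training individuals; omit it to score the training set itself.
    Returns (mu, predicted phenotype = X_new b + mu).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    Kt = K_train.K if isinstance(K_train, KinshipMatrix) else np.asarray(K_train, float)
    if K_cross is None:
        K_cross = Kt
    K_cross = np.asarray(K_cross, dtype=float)
    if X_new is None:
        X_new = np.ones((K_cross.shape[0], X.shape[1]))
    V = vc.sigma_g2 * Kt + vc.sigma_e2 * np.eye(n)
    resid = y - X @ vc.beta
    alpha = np.linalg.solve(V, resid)
    mu = vc.sigma_g2 * (K_cross @ alpha)
    return mu, X_new @ vc.beta + mu


class GBLUP:
    """Genomic BLUP mixed model for one or more traits over one kinship.

    Parameters
    ----------
    endog : (n,) vector or (n, d) matrix or PhenotypeTable of phenotypes
    kinship : KinshipMatrix, (n, n) array, or precomputed ``(eigvals, eigvecs)``
    exog : optional fixed-effect design (default: intercept only)

    The kinship is eigendecomposed once at construction; ``fit`` then costs
    one rotation and a 1-D likelihood search per trait.
    """

    def __init__(self, endog, kinship, exog=None):
        if isinstance(endog, PhenotypeTable):
            if endog.missing.any():
                raise ValueError("phenotypes must be complete for GBLUP")
            self.trait_names = list(endog.trait_names)
            self.individual_ids = list(endog.individual_ids)
            Y = endog.values
        else:
            Y = np.asarray(endog, dtype=float)
            if Y.ndim == 1:
                Y = Y[:, None]
            self.trait_names = [f"y{j}" for j in range(Y.shape[1])]
            self.individual_ids = (
                list(kinship.individual_ids)
                if isinstance(kinship, KinshipMatrix)
                else [str(i) for i in range(Y.shape[0])]
            )
        self.endog = Y
        n = Y.shape[0]
        self.exog = np.ones((n, 1)) if exog is None else np.atleast_2d(
            np.asarray(exog, float)
        )
        self._lam, self._U = _as_eig(
            kinship if not isinstance(kinship, KinshipMatrix) else kinship.K, n
        )
        self.kinship = kinship

    def fit(self, h2_tol: float = 1e-8) -> "GBLUPResults":
        vcs = [
            reml_fit(self.endog[:, j], (self._lam, self._U), self.exog, h2_tol)
            for j in range(self.endog.shape[1])
        ]
        return GBLUPResults(self, vcs)


class GBLUPResults:
    """Fitted variance components and BLUP predictor for each trait."""

    def __init__(self, model: GBLUP, components: list[VarianceComponents]):
        self.model = model
        self.components = components

    @property
    def h2(self) -> np.ndarray:
        return np.array([vc.h2 for vc in self.components])

    @property
    def sigma_g2(self) -> np.ndarray:
        return np.array([vc.sigma_g2 for vc in self.components])

    @property
    def sigma_e2(self) -> np.ndarray:
        return np.array([vc.sigma_e2 for vc in self.components])

    def predict(self, K_cross=None, exog_new=None) -> np.ndarray:
        """Predicted phenotypes (fixed effects + BLUP genetic values)."""
        K = self.model.kinship
        Kt = K.K if isinstance(K, KinshipMatrix) else (
            None if isinstance(K, tuple) else np.asarray(K, float)
        )
        if Kt is None:
            lam, U = self.model._lam, self.model._U
            Kt = (U * lam) @ U.T
        out = np.column_stack(
            [
                gblup_predict(
                    self.model.endog[:, j],
                    Kt,
                    vc,
                    X=self.model.exog,
                    K_cross=K_cross,
                    X_new=exog_new,
                )[1]
                for j, vc in enumerate(self.components)
            ]
        )
        return out

    def summary(self) -> str:
        df = pd.DataFrame(
            {
                "trait": self.model.trait_names,
                "sigma_g2": self.sigma_g2,
                "sigma_e2": self.sigma_e2,
                "h2": self.h2,
                "loglike_reml": [vc.loglike for vc in self.components],
            }
        )
        header = "GBLUP mixed model (REML profile over h2)\n"
        header += f"n = {self.model.endog.shape[0]}, traits = {len(self.components)}\n"
        return header + df.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def prediction_accuracy(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    observed = np.asarray(observed, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if observed.size != predicted.size:
        raise ValueError("length mismatch")
    if observed.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(observed, predicted)[0])


def _fold_assignment(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then contiguous near-equal blocks; remainders are
    distributed one per fold starting from the first."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    sizes = [base + (1 if f < rem else 0) for f in range(k)]
    folds, start = [], 0
    for s in sizes:
        folds.append(np.sort(order[start : start + s]))
        start += s
    return folds


def kfold_self_predictions(
    phenotypes: PhenotypeTable,
    kinship: KinshipMatrix,
    k: int = 10,
    seed: int = 0,
    ids=None,
) -> PredictionSet:
    """Within-training-set genomic predictions by k-fold cross-validation.

    Each individual is predicted exactly once, from a GBLUP model fitted on
    the folds excluding it; the default of 10 folds follows common practice
    for ~hundreds of training hybrids.  The paired observed/predicted matrix
    is the input the similarity learner trains on.
    """
    if ids is not None:
        phenotypes = phenotypes.subset(ids)
        kinship = kinship.submatrix(list(ids))
    if phenotypes.missing.any():
        raise ValueError("phenotypes must be complete")
    n = phenotypes.n_individuals
    if not 2 <= k <= n:
        raise ValueError("k must lie in [2, n]")
    folds = _fold_assignment(n, k, seed)
    if min(len(f) for f in folds) < 1 or n - max(len(f) for f in folds) < 2:
        raise ValueError("folds too small for model fitting")
    Y = phenotypes.values
    predicted = np.empty_like(Y)
    for fold in folds:
        rest = np.setdiff1d(np.arange(n), fold)
        K_rr = kinship.K[np.ix_(rest, rest)]
        lam, U = np.linalg.eigh(K_rr)
        eig = (np.clip(lam, 0.0, None), U)
        K_fr = kinship.K[np.ix_(fold, rest)]
        for j in range(Y.shape[1]):
            vc = reml_fit(Y[rest, j], eig, None)
            _, yhat = gblup_predict(Y[rest, j], K_rr, vc, K_cross=K_fr)
            predicted[fold, j] = yhat
    return PredictionSet(
        list(phenotypes.individual_ids),
        list(phenotypes.trait_names),
        Y,
        predicted,
    )
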