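"""Synthetic NCII factorial populations with controlled genetic architecture.

The generator emulates the structure of a hybrid-maize NCII panel: a set of
fully inbred maternal and paternal parents, the complete M x P grid of F1
hybrids (dosage = mean of the parental dosages), multi-trait phenotypes built
from shared additive QTL with target heritabilities and cross-trait genetic
correlations, and optional omics feature layers that are partially under
genetic control.  Everything is a pure function of (config, seed).

Defaults mirror a maize NCII panel: 194 maternal x 30 paternal inbreds
(5820 hybrids), 10 traits with heritabilities spread over [0.3, 0.8], trait
mean 100 with phenotypic SD 10 (a 10% coefficient of variation, typical of
flowering-time or plant-height scales, so a 5% ideotype shift equals half a
phenotypic SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MatingDesign, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_ncii_genotypes",
    "simulate_phenotypes",
    "simulate_omics_layers",
    "diagonal_training_split",
]


def _default_h2() -> np.ndarray:
    return np.linspace(0.3, 0.8, 10)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic NCII study.

    ``genetic_correlation`` defaults to an exchangeable matrix with
    off-diagonal 0.2 (agronomic traits are mildly correlated); pass the
    identity for independent genetic architectures.
    """

    n_maternal: int = 194
    n_paternal: int = 30
    n_markers: int = 1000
    n_qtl: int = 100
    h2: np.ndarray = field(default_factory=_default_h2)
    genetic_correlation: np.ndarray | None = None
    trait_mean: float = 100.0
    phenotype_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        self.h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if np.any(self.h2 <= 0) or np.any(self.h2 > 1):
            raise ValueError("heritabilities must lie in (0, 1]")
        d = self.h2.size
        if self.genetic_correlation is None:
            self.genetic_correlation = np.full((d, d), 0.2) + 0.8 * np.eye(d)
        self.genetic_correlation = np.asarray(self.genetic_correlation, dtype=float)
        if self.genetic_correlation.shape != (d, d):
            raise ValueError("genetic_correlation must be d x d")
        if not np.allclose(self.genetic_correlation, self.genetic_correlation.T):
            raise ValueError("genetic_correlation must be symmetric")
        if not np.allclose(np.diag(self.genetic_correlation), 1.0):
            raise ValueError("genetic_correlation must have unit diagonal")
        if np.linalg.eigvalsh(self.genetic_correlation).min() < -1e-10:
            raise ValueError("genetic_correlation must be positive semi-definite")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.n_maternal * self.n_paternal < 2:
            raise ValueError("mating design must produce at least 2 hybrids")

    @property
    def n_traits(self) -> int:
        return self.h2.size

    @property
    def trait_names(self) -> list[str]:
        return [f"trait{j + 1:02d}" for j in range(self.n_traits)]


@dataclass
class TruthSet:
    """Ground truth behind a simulated phenotype table."""

    individual_ids: list[str]
    trait_names: list[str]
    genetic_values: np.ndarray  # n x d, on the phenotype scale
    qtl_indices: np.ndarray  # shared QTL marker indices
    qtl_effects: np.ndarray  # n_qtl x d, post-scaling
    realized_h2: np.ndarray  # per-trait Var(g)/Var(y)

    def genetic_value_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genetic_values, index=self.individual_ids, columns=self.trait_names
        )


def simulate_ncii_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, MatingDesign]:
    """Draw parental inbreds and the full grid of F1 hybrid dosages.

    Each marker's allele frequency is uniform on [0.1, 0.9] (keeps MAF away
    from filtering thresholds); parents are sampled as homozygotes (dosage 0
    or 2), so every hybrid dosage is the parental mean and lies in {0, 1, 2}.
    """
    rng = np.random.default_rng(config.seed)
    M, P, m = config.n_maternal, config.n_paternal, config.n_markers
    freqs = rng.uniform(0.1, 0.9, size=m)
    maternal = 2.0 * (rng.random((M, m)) < freqs)
    paternal = 2.0 * (rng.random((P, m)) < freqs)

    design = MatingDesign(
        [f"M{i + 1:03d}" for i in range(M)], [f"P{j + 1:02d}" for j in range(P)]
    )
    marker_ids = [f"snp{k + 1:05d}" for k in range(m)]
    parents = GenotypeMatrix(
        design.maternal_ids + design.paternal_ids,
        marker_ids,
        np.vstack([maternal, paternal]),
    )
    # hybrid dosage = (maternal + paternal) / 2, maternal-major row order
    hyb = (maternal[:, None, :] + paternal[None, :, :]) / 2.0
    hybrids = GenotypeMatrix(
        design.hybrid_ids(), marker_ids, hyb.reshape(M * P, m)
    )
    return parents, hybrids, design


def simulate_phenotypes(
    hybrids: GenotypeMatrix, config: SimulationConfig, seed: int | None = None
) -> tuple[PhenotypeTable, TruthSet]:
    """Additive multi-trait phenotypes with target heritabilities.

    All traits share one set of QTL; per-QTL effect vectors are drawn from a
    multivariate normal with the configured cross-trait correlation, which
    induces the genetic correlation between trait pairs.  Genetic values are
    rescaled to variance h2 * phenotype_sd**2 and iid Gaussian noise supplies
    the residual variance, so the population-level variance ratio matches the
    target heritability up to noise-sampling error.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    d = config.n_traits
    qtl = rng.choice(hybrids.n_markers, size=config.n_qtl, replace=False)
    chol = np.linalg.cholesky(
        config.genetic_correlation + 1e-12 * np.eye(d)
    )
    effects = rng.standard_normal((config.n_qtl, d)) @ chol.T
    W = hybrids.dosages[:, qtl]
    g = (W - W.mean(axis=0)) @ effects

    g_sd = g.std(axis=0, ddof=0)
    if np.any(g_sd == 0):
        raise ValueError("degenerate genetic values; increase n_qtl or markers")
    target_g_sd = np.sqrt(config.h2) * config.phenotype_sd
    scale = target_g_sd / g_sd
    g *= scale
    effects *= scale

    noise_sd = np.sqrt(1.0 - config.h2) * config.phenotype_sd
    y = config.trait_mean + g + rng.standard_normal(g.shape) * noise_sd

    var_y = y.var(axis=0, ddof=0)
    realized = g.var(axis=0, ddof=0) / var_y
    phenotypes = PhenotypeTable(list(hybrids.individual_ids), config.trait_names, y)
    truth = TruthSet(
        list(hybrids.individual_ids),
        config.trait_names,
        config.trait_mean + g,
        qtl,
        effects,
        realized,
    )
    return phenotypes, truth


def simulate_omics_layers(
    hybrids: GenotypeMatrix,
    n_features: int,
    genetic_fraction: float,
    seed: int,
    markers_per_feature: int = 5,
) -> pd.DataFrame:
    """Omics feature layer partially coupled to the genotypes.

    Each feature is a linear combination of a few marker dosages contributing
    a ``genetic_fraction`` share of its variance, plus Gaussian noise;
    ``genetic_fraction=0`` yields pure-noise features (useful for exercising
    trait filtering) and ``genetic_fraction=1`` exact linear functions of the
    dosages.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not 0.0 <= genetic_fraction <= 1.0:
        raise ValueError("genetic_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = hybrids.n_individuals
    out = np.empty((n, n_features))
    for f in range(n_features):
        signal = np.zeros(n)
        if genetic_fraction > 0:
            cols = rng.choice(hybrids.n_markers, size=markers_per_feature, replace=False)
            coefs = rng.standard_normal(markers_per_feature)
            signal = hybrids.dosages[:, cols] @ coefs
            signal = signal - signal.mean()
            sd = signal.std()
            if sd > 0:
                signal /= sd
        noise = rng.standard_normal(n)
        out[:, f] = np.sqrt(genetic_fraction) * signal + np.sqrt(
            1.0 - genetic_fraction
        ) * noise
    return pd.DataFrame(
        out,
        index=hybrids.individual_ids,
        columns=[f"feature{f + 1:04d}" for f in range(n_features)],
    )


def diagonal_training_split(
    design: MatingDesign,
    n_strips: int,
    target_size: int | None = None,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Wrap-around diagonal-strip training design on the NCII grid.

    Strip s collects every hybrid (i, j) with j = (i + s) mod P, so each
    maternal parent appears exactly ``n_strips`` times in training and the
    design stays maximally connected.  ``target_size`` optionally trims the
    training set to an exact count by seeded random removal (e.g. to emulate
    a published 569-hybrid three-strip scheme that a full-diagonal convention
    cannot produce on a 194 x 30 grid).
    """
    P = design.n_paternal
    if not 1 <= n_strips <= P:
        raise ValueError(f"n_strips must lie in [1, {P}]")
    train = [
        design.hybrid_id(i, (i + s) % P)
        for s in range(n_strips)
        for i in range(design.n_maternal)
    ]
    train = sorted(set(train), key=train.index)
    if target_size is not None:
        if target_size > len(train):
            raise ValueError("target_size exceeds the strip training set")
        rng = np.random.default_rng(0 if seed is None else seed)
        drop = set(rng.choice(len(train), size=len(train) - target_size, replace=False))
        train = [h for k, h in enumerate(train) if k not in drop]
    train_set = set(train)
    test = [h for h in design.hybrid_ids() if h not in train_set]
    return train, test
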