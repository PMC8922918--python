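"""End-to-end NCII study: simulate, predict, learn weights, evaluate.

Ties the stages together the way a breeding analysis would run them: simulate
(or load) an NCII hybrid population, pick a diagonal-strip training set,
produce k-fold self-predictions inside the training set for weight learning,
predict the testing set with GBLUP trained on the full training set, then
learn similarity weights and measure identification rates.  Kinship blocks
are computed directly from centered dosages so the full hybrid-by-hybrid
matrix is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MatingDesign, PhenotypeTable, PredictionSet, TraitWeights
from .gblup import (
    KinshipMatrix,
    centered_dosages,
    kfold_self_predictions,
    reml_fit,
    gblup_predict,
)
from .simulate import (
    SimulationConfig,
    TruthSet,
    diagonal_training_split,
    simulate_ncii_genotypes,
    simulate_phenotypes,
)
from .top import TOPModel, TOPResults

__all__ = ["NCIIStudy", "run_ncii_study", "predict_testing_set"]


def predict_testing_set(
    dosages: np.ndarray,
    phenotypes: PhenotypeTable,
    train_idx,
    test_idx,
) -> PredictionSet:
    """GBLUP predictions for a testing set from a phenotyped training set.

    Fits REML per trait on the training block (one shared eigendecomposition)
    and applies the BLUP equation through the train/test kinship block.
    """
    Wc, keep = centered_dosages(np.asarray(dosages, float))
    m = int(keep.sum())
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    K_tt = Wc[train_idx] @ Wc[train_idx].T / m
    K_xt = Wc[test_idx] @ Wc[train_idx].T / m
    lam, U = np.linalg.eigh(K_tt)
    eig = (np.clip(lam, 0.0, None), U)
    Y = phenotypes.values
    predicted = np.empty((test_idx.size, Y.shape[1]))
    for j in range(Y.shape[1]):
        y = Y[train_idx, j]
        vc = reml_fit(y, eig, None)
        _, predicted[:, j] = gblup_predict(y, K_tt, vc, K_cross=K_xt)
    ids = [phenotypes.individual_ids[i] for i in test_idx]
    return PredictionSet(ids, list(phenotypes.trait_names), Y[test_idx], predicted)


@dataclass
class NCIIStudy:
    """All artifacts of one simulated NCII analysis round."""

    config: SimulationConfig
    design: MatingDesign
    phenotypes: PhenotypeTable
    truth: TruthSet
    train_ids: list[str]
    test_ids: list[str]
    training_predictions: PredictionSet  # k-fold self-predictions
    testing_predictions: PredictionSet  # GBLUP from the full training set
    top_results: TOPResults

    @property
    def weights(self) -> TraitWeights:
        return self.top_results.weights


def run_ncii_study(
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_strips: int = 3,
    kfold: int = 10,
    training_size: int | None = None,
) -> NCIIStudy:
    """Run the full synthetic pipeline under one seed.

    ``n_strips`` diagonal strips of the mating grid form the training set;
    self-predictions inside it come from ``kfold``-fold cross-validation, and
    similarity weights are learned on those pairs starting from all-ones.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    else:
        config = SimulationConfig(
            n_maternal=config.n_maternal,
            n_paternal=config.n_paternal,
            n_markers=config.n_markers,
            n_qtl=config.n_qtl,
            h2=config.h2,
            genetic_correlation=config.genetic_correlation,
            trait_mean=config.trait_mean,
            phenotype_sd=config.phenotype_sd,
            seed=seed,
        )
    _, hybrids, design = simulate_ncii_genotypes(config)
    phenotypes, truth = simulate_phenotypes(hybrids, config)
    train_ids, test_ids = diagonal_training_split(
        design, n_strips, target_size=training_size, seed=seed
    )
    pos = {h: i for i, h in enumerate(hybrids.individual_ids)}
    train_idx = np.array([pos[h] for h in train_ids])
    test_idx = np.array([pos[h] for h in test_ids])

    Wc, keep = centered_dosages(hybrids.dosages)
    K_tt = KinshipMatrix(train_ids, Wc[train_idx] @ Wc[train_idx].T / keep.sum())
    training_predictions = kfold_self_predictions(
        phenotypes.subset(train_ids), K_tt, k=kfold, seed=seed
    )
    testing_predictions = predict_testing_set(
        hybrids.dosages, phenotypes, train_idx, test_idx
    )
    top_results = TOPModel(training_predictions).fit()
    return NCIIStudy(
        config,
        design,
        phenotypes,
        truth,
        train_ids,
        test_ids,
        training_predictions,
        testing_predictions,
        top_results,
    )
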