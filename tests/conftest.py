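import numpy as np
import pytest

from topsel import (
    SimulationConfig,
    compute_kinship,
    kfold_self_predictions,
    simulate_ncii_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A 20 x 8 NCII design: big enough for GBLUP to have signal, small
    enough that every test stage runs in well under a second."""
    return SimulationConfig(
        n_maternal=20,
        n_paternal=8,
        n_markers=300,
        n_qtl=80,
        h2=np.array([0.4, 0.6, 0.8]),
        genetic_correlation=np.eye(3),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    parents, hybrids, design = simulate_ncii_genotypes(small_config)
    phenotypes, truth = simulate_phenotypes(hybrids, small_config)
    return {
        "config": small_config,
        "parents": parents,
        "hybrids": hybrids,
        "design": design,
        "phenotypes": phenotypes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_prediction_set(small_population):
    """5-fold self-predictions over the 160 hybrids of the small design."""
    K = compute_kinship(small_population["hybrids"])
    return kfold_self_predictions(
        small_population["phenotypes"], K, k=5, seed=7
    )
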