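"""Pool-based identification-rate protocol and its chance baseline.

The accuracy metric of target-oriented prioritization: sample pools of N0
individuals from the testing population, treat each pool member in turn as
the target (its *observed* phenotypes define the profile to match), rank all
pool members by similarity computed on their *predicted* phenotypes, and
count the trial a success when the target itself ranks first.  The rate is
successes over trials, and the chance baseline for a pool of N0 is 1/N0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .top import pairwise_weighted_l1

__all__ = [
    "IdentificationReport",
    "identification_rate",
    "random_baseline",
    "pool_sweep",
]


def random_baseline(pool_size: int) -> float:
    """Probability of identifying the target from an N-sized pool by chance."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return 1.0 / pool_size


def _pool_successes(obs, pred, w, ids) -> int:
    """Count members of one pool that identify themselves.

    Success requires the member's own prediction to win the softmax ranking,
    i.e. attain the strictly smallest weighted distance; exact ties are
    resolved by the deterministic id tie-break, so a tied target only wins
    with the lexicographically smallest id among the tied set.
    """
    D = pairwise_weighted_l1(obs, pred, w)
    n = D.shape[0]
    successes = 0
    for i in range(n):
        row = D[i]
        mn = row.min()
        if row[i] > mn:
            continue
        tied = np.flatnonzero(row == mn)
        if tied.size == 1 or min((ids[t] for t in tied)) == ids[i]:
            successes += 1
    return successes


def identification_rate(
    observed,
    predicted,
    w,
    pool_size: int,
    n_pools: int = 200,
    seed: int = 0,
    ids=None,
) -> float:
    """Monte-Carlo identification rate at one pool size.

    Pools are sampled without replacement within each pool and independently
    across pools; every member of every pool serves once as the target.
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    N = observed.shape[0]
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    if pool_size > N:
        raise ValueError("pool_size exceeds population size")
    if ids is None:
        ids = [f"{i:06d}" for i in range(N)]
    ids = [str(x) for x in ids]
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_pools):
        pool = rng.choice(N, size=pool_size, replace=False)
        total += _pool_successes(
            observed[pool], predicted[pool], w, [ids[i] for i in pool]
        )
    return total / (n_pools * pool_size)


@dataclass
class IdentificationReport:
    """Identification rates across pool sizes with the chance baseline."""

    pool_sizes: list[int]
    rates: np.ndarray
    baselines: np.ndarray
    n_pools: int
    seed: int

    def __post_init__(self):
        self.rates = np.asarray(self.rates, float)
        self.baselines = np.asarray(self.baselines, float)
        if np.any(self.rates < 0) or np.any(self.rates > 1):
            raise ValueError("rates must lie in [0, 1]")

    @property
    def improvement(self) -> np.ndarray:
        """Fold improvement of the identification rate over chance."""
        return self.rates / self.baselines

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pool_size": self.pool_sizes,
                "identification_rate": self.rates,
                "random_baseline": self.baselines,
                "improvement": self.improvement,
            }
        )


def pool_sweep(
    observed,
    predicted,
    w,
    pool_sizes,
    n_pools: int = 200,
    seed: int = 0,
    ids=None,
) -> IdentificationReport:
    """Identification rate at each pool size, with baseline and fold gain."""
    pool_sizes = [int(s) for s in pool_sizes]
    rates = [
        identification_rate(
            observed, predicted, w, s, n_pools=n_pools, seed=seed + k, ids=ids
        )
        for k, s in enumerate(pool_sizes)
    ]
    baselines = [random_baseline(s) for s in pool_sizes]
    return IdentificationReport(pool_sizes, np.array(rates), np.array(baselines), n_pools, seed)
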