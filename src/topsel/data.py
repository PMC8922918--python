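"""Core in-memory containers shared across the toolkit.

Genotypes are held as additive allele dosages (0/1/2 copies of the counted
allele), phenotypes and omics features as individuals x named-columns real
matrices.  All containers validate their invariants on construction and are
cheap views over numpy arrays; conversion to/from pandas is provided for I/O
and interactive work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "PredictionSet",
    "MatingDesign",
    "SelectionResult",
    "TraitWeights",
]


def _check_unique(labels, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    return labels


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive dosage matrix.

    Parameters
    ----------
    individual_ids : ordered unique labels, length n (n >= 2)
    marker_ids : ordered unique labels, length m (m >= 1)
    dosages : (n, m) array; non-missing entries in {0, 1, 2}.  Entries that
        were missing on input are mean-imputed and flagged in ``missing``.
    missing : optional (n, m) boolean mask of originally-missing entries
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.individual_ids = _check_unique(self.individual_ids, "individual")
        self.marker_ids = _check_unique(self.marker_ids, "marker")
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.individual_ids), len(self.marker_ids)
        if n < 2:
            raise ValueError("need at least 2 individuals")
        if m < 1:
            raise ValueError("need at least 1 marker")
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match ids ({n}, {m})"
            )
        if self.missing is None:
            self.missing = np.zeros((n, m), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, m):
                raise ValueError("missing mask shape mismatch")
        observed = self.dosages[~self.missing]
        if not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individual_ids, columns=self.marker_ids
        )

    def subset(self, individual_ids) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in individual_ids]
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            list(self.marker_ids),
            self.dosages[idx],
            self.missing[idx],
        )


@dataclass
class PhenotypeTable:
    """Individuals x named traits real matrix with a missing-value mask."""

    individual_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.individual_ids = _check_unique(self.individual_ids, "individual")
        self.trait_names = _check_unique(self.trait_names, "trait")
        self.values = np.asarray(self.values, dtype=float)
        n, d = len(self.individual_ids), len(self.trait_names)
        if d < 1:
            raise ValueError("need at least 1 trait")
        if self.values.shape != (n, d):
            raise ValueError("phenotype shape mismatch")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.trait_names
        )
        return df.mask(pd.DataFrame(self.missing, index=df.index, columns=df.columns))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhenotypeTable":
        values = df.to_numpy(dtype=float)
        return cls(list(df.index), list(df.columns), values, ~np.isfinite(values))

    def subset(self, individual_ids) -> "PhenotypeTable":
        pos = {v: i for i, v in enumerate(self.individual_ids)}
        idx = [pos[i] for i in individual_ids]
        return PhenotypeTable(
            [self.individual_ids[i] for i in idx],
            list(self.trait_names),
            self.values[idx],
            self.missing[idx],
        )


@dataclass
class PredictionSet:
    """Paired observed / genomically predicted trait values for one set of
    individuals — the training fuel of the similarity learner.

    Both matrices share shape, individual order and trait order and must be
    complete (no missing entries).
    """

    individual_ids: list[str]
    trait_names: list[str]
    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        self.individual_ids = _check_unique(self.individual_ids, "individual")
        self.trait_names = _check_unique(self.trait_names, "trait")
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        shape = (len(self.individual_ids), len(self.trait_names))
        if self.observed.shape != shape or self.predicted.shape != shape:
            raise ValueError("observed/predicted shape mismatch")
        if not (np.isfinite(self.observed).all() and np.isfinite(self.predicted).all()):
            raise ValueError("PredictionSet must be complete (no missing values)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def accuracies(self) -> np.ndarray:
        """Per-trait Pearson correlation between observed and predicted."""
        from .gblup import prediction_accuracy

        return np.array(
            [
                prediction_accuracy(self.observed[:, j], self.predicted[:, j])
                for j in range(self.n_traits)
            ]
        )

    def select_traits(self, names) -> "PredictionSet":
        idx = [self.trait_names.index(t) for t in names]
        return PredictionSet(
            list(self.individual_ids),
            [self.trait_names[j] for j in idx],
            self.observed[:, idx],
            self.predicted[:, idx],
        )

    def subset(self, individual_ids) -> "PredictionSet":
        pos = {v: i for i, v in enumerate(self.individual_ids)}
        idx = [pos[i] for i in individual_ids]
        return PredictionSet(
            [self.individual_ids[i] for i in idx],
            list(self.trait_names),
            self.observed[idx],
            self.predicted[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        obs = pd.DataFrame(
            self.observed,
            index=self.individual_ids,
            columns=[f"{t}_obs" for t in self.trait_names],
        )
        pred = pd.DataFrame(
            self.predicted,
            index=self.individual_ids,
            columns=[f"{t}_pred" for t in self.trait_names],
        )
        return pd.concat([obs, pred], axis=1)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PredictionSet":
        traits = [c[:-4] for c in df.columns if c.endswith("_obs")]
        return cls(
            list(df.index),
            traits,
            df[[f"{t}_obs" for t in traits]].to_numpy(),
            df[[f"{t}_pred" for t in traits]].to_numpy(),
        )


@dataclass
class MatingDesign:
    """Full factorial (NCII) mating grid: every maternal inbred crossed to
    every paternal inbred, hybrids indexed by (maternal, paternal) position."""

    maternal_ids: list[str]
    paternal_ids: list[str]

    def __post_init__(self):
        self.maternal_ids = _check_unique(self.maternal_ids, "maternal")
        self.paternal_ids = _check_unique(self.paternal_ids, "paternal")
        if self.n_hybrids < 2:
            raise ValueError("design must produce at least 2 hybrids")

    @property
    def n_maternal(self) -> int:
        return len(self.maternal_ids)

    @property
    def n_paternal(self) -> int:
        return len(self.paternal_ids)

    @property
    def n_hybrids(self) -> int:
        return self.n_maternal * self.n_paternal

    def hybrid_id(self, i: int, j: int) -> str:
        return f"{self.maternal_ids[i]}x{self.paternal_ids[j]}"

    def hybrid_ids(self) -> list[str]:
        # maternal-major ordering, matching the simulated dosage row order
        return [
            self.hybrid_id(i, j)
            for i in range(self.n_maternal)
            for j in range(self.n_paternal)
        ]

    def position(self, hybrid_id: str) -> tuple[int, int]:
        mat, pat = hybrid_id.split("x")
        return self.maternal_ids.index(mat), self.paternal_ids.index(pat)


@dataclass
class TraitWeights:
    """Learned per-trait weights of the similarity function."""

    trait_names: list[str]
    w: np.ndarray
    converged: bool = True
    grad_norm: float = 0.0
    n_iter: int = 0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.trait_names),):
            raise ValueError("weight length does not match trait count")
        if not np.isfinite(self.w).all():
            raise ValueError("weights must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=self.trait_names, name="weight")


@dataclass
class SelectionResult:
    """Candidates ordered by descending similarity to a target profile.

    Scores are softmax-normalised over the candidate pool, so they are
    positive and sum to one; ties are broken by candidate id.
    """

    target_label: str
    candidate_ids: list[str]
    scores: np.ndarray
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.candidate_ids) != self.scores.size:
            raise ValueError("ids/scores length mismatch")
        if len(self.candidate_ids) == 0:
            raise ValueError("empty selection result")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.candidate_ids)

    def top(self, k: int) -> list[str]:
        return self.candidate_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.candidate_ids) + 1),
                "candidate_id": self.candidate_ids,
                "score": self.scores,
            }
        )
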