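"""Ideotype construction and target-directed candidate selection.

A target is a reference variety's phenotype profile (e.g. a commercial check
hybrid) with selected traits shifted multiplicatively — "flower 5% earlier"
is a 0.95 factor on days-to-tassel with every other trait held at the
reference value.  Candidates most similar to the modified profile are
selected with the learned similarity, and two scores summarise the outcome:
the fraction of selected candidates on the intended side of the reference
(directional success) and the mean squared difference to the reference over
the unmodified traits (global similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SelectionResult, TraitWeights
from .top import rank_candidates

__all__ = [
    "TargetSpec",
    "make_modified_target",
    "select_candidates_for_target",
    "global_mse_similarity",
    "directional_success_rate",
]


@dataclass
class TargetSpec:
    """A reference phenotype profile with per-trait multiplicative modifiers."""

    trait_names: list[str]
    base: np.ndarray
    modifiers: dict = field(default_factory=dict)
    label: str = "target"

    def __post_init__(self):
        self.base = np.asarray(self.base, float).ravel()
        if self.base.size != len(self.trait_names):
            raise ValueError("base profile length mismatch")
        for trait, factor in self.modifiers.items():
            if trait not in self.trait_names:
                raise KeyError(f"unknown trait {trait!r} in modifiers")
            if factor <= 0:
                raise ValueError("modifiers must be positive factors")

    @property
    def values(self) -> np.ndarray:
        out = self.base.copy()
        for trait, factor in self.modifiers.items():
            out[self.trait_names.index(trait)] *= factor
        return out

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.trait_names, name=self.label)


def make_modified_target(base, modifiers: dict | None = None, trait_names=None,
                         label: str = "target") -> TargetSpec:
    """Build a TargetSpec from a reference profile and trait->factor map.

    An empty modifier map returns the reference itself (the control case of
    including the check variety as its own target).
    """
    if isinstance(base, pd.Series):
        trait_names = [str(t) for t in base.index]
        base = base.to_numpy(float)
    elif trait_names is None:
        raise ValueError("trait_names required when base is not a named Series")
    return TargetSpec(list(trait_names), np.asarray(base, float),
                      dict(modifiers or {}), label)


def select_candidates_for_target(
    target: TargetSpec,
    candidate_predictions,
    w: TraitWeights,
    k: int,
    candidate_ids,
) -> SelectionResult:
    """Top-k candidates most similar to the (modified) target profile."""
    preds = np.atleast_2d(np.asarray(candidate_predictions, float))
    if k > preds.shape[0] or k < 1:
        raise ValueError("k must lie in [1, N]")
    full = rank_candidates(target.values, preds, w, candidate_ids, label=target.label)
    return SelectionResult(
        target_label=full.target_label,
        candidate_ids=full.candidate_ids[:k],
        scores=full.scores[:k],
        trait_names=full.trait_names,
    )


def global_mse_similarity(
    candidate,
    reference,
    excluded_traits=(),
    trait_names=None,
    scale_sd=None,
) -> float:
    """Mean squared difference to the reference over non-excluded traits.

    By default each trait is z-scaled by a testing-population SD
    (``scale_sd``) before squaring so heterogeneous units do not dominate;
    pass ``scale_sd=None``-equivalent ones for a raw-scale MSE.  Lower values
    mean higher global similarity to the reference variety.
    """
    if isinstance(candidate, pd.Series):
        trait_names = [str(t) for t in candidate.index]
        candidate = candidate.to_numpy(float)
    candidate = np.asarray(candidate, float).ravel()
    reference = np.asarray(
        reference.to_numpy(float) if isinstance(reference, pd.Series) else reference,
        float,
    ).ravel()
    if trait_names is None:
        trait_names = [str(i) for i in range(candidate.size)]
    excluded = set(excluded_traits)
    unknown = excluded - set(trait_names)
    if unknown:
        raise KeyError(f"excluded traits not present: {sorted(unknown)}")
    keep = np.array([t not in excluded for t in trait_names])
    if not keep.any():
        raise ValueError("all traits excluded from the similarity")
    diff = candidate[keep] - reference[keep]
    if scale_sd is not None:
        sd = np.asarray(scale_sd, float).ravel()[keep]
        if np.any(sd <= 0):
            raise ValueError("scale SDs must be positive")
        diff = diff / sd
    return float(np.mean(diff**2))


def directional_success_rate(selected_values, reference_value: float,
                             direction: str) -> float:
    """Fraction of selected candidates strictly beyond the reference in the
    requested direction ('greater' or 'less')."""
    values = np.asarray(selected_values, float).ravel()
    if values.size == 0:
        raise ValueError("empty selection")
    if direction == "greater":
        return float(np.mean(values > reference_value))
    if direction == "less":
        return float(np.mean(values < reference_value))
    raise ValueError("direction must be 'greater' or 'less'")
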