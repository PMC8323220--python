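"""Soft-voting ensemble over the single models' softmax outputs.

Each of the K members contributes a matrix M^i of per-sample class
probabilities; the ensemble prediction for a sample is the argmax of the
equally weighted member mean.  Ties break to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .train import TrainedModel


@dataclass(frozen=True)
class EnsembleOutput:
    """Member probability matrices, their mean, and the voted predictions."""

    member_probabilities: tuple[np.ndarray, ...]
    averaged: np.ndarray
    predictions: np.ndarray


def soft_vote(member_probabilities: Sequence[np.ndarray]) -> EnsembleOutput:
    """Average K member probability matrices and take the per-row argmax.

    All matrices must share shape and have rows summing to 1 within 1e-6.
    np.argmax returns the first maximal index, which implements the
    lowest-class-index tie rule.
    """
    if len(member_probabilities) < 1:
        raise ValueError("need at least one member")
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in member_probabilities]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("member probability matrices must share shape")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6) or np.any(m < -1e-9):
            raise ValueError("rows must be valid probability vectors")
    averaged = np.mean(mats, axis=0)
    return EnsembleOutput(
        member_probabilities=tuple(mats),
        averaged=averaged,
        predictions=averaged.argmax(axis=1),
    )


def predict_ensemble(
    models: Sequence[TrainedModel], texts: Sequence[str]
) -> EnsembleOutput:
    """Run every member's forward pass on the texts and soft-vote.

    All members must share one category schema; each tokenizes with its own
    vocabulary and encoder configuration.
    """
    if len(models) < 1:
        raise ValueError("need at least one trained model")
    schema = models[0].schema
    for m in models[1:]:
        if m.schema != schema:
            raise ValueError("ensemble members must share a category schema")
    member_probs = [m.predict_proba(list(texts)) for m in models]
    return soft_vote(member_probs)
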