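"""Deterministic core of the continuous-criterion exemplar model.

The model is the context model of Medin & Schaffer extended to a continuous
judgment criterion (Juslin-style multiple-cue judgment): stimuli are vectors
of ``D`` binary cues, similarity between a probe and a stored exemplar is the
product of per-cue factors (1 on a match, ``s`` on a mismatch, hence
``s ** (D - m)`` with ``m`` matching cues), and the judged criterion of a
probe is the similarity-weighted average of the stored exemplar criteria.

``s`` lives on [0, 1]: small values mean sharp discrimination between
exemplars (only near-matches influence the judgment), ``s = 1`` means no
discrimination at all (every probe is judged as the plain mean of the stored
criteria).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExemplarMemory",
    "ModelParams",
    "UndefinedPredictionError",
    "as_cue_vector",
    "similarity",
    "predict_criterion",
    "predict_batch",
    "mismatch_counts",
]


class UndefinedPredictionError(ValueError):
    """Raised when the similarity-weighted average has a zero denominator.

    This happens for ``s = 0`` when no stored exemplar exactly matches the
    probe: similarity to every exemplar is 0 and the model makes no
    prediction (judgments would be erratic).
    """


def as_cue_vector(values: Sequence[float] | np.ndarray, *, name: str = "cue vector") -> np.ndarray:
    """Validate and convert a sequence of binary cues to an int array."""
    arr = np.asarray(values)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D sequence, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))][0]
        raise ValueError(f"{name} must contain only binary cues 0/1, found {bad!r}")
    return arr.astype(np.int64)


def _as_cue_matrix(rows: np.ndarray | Sequence[Sequence[float]], *, name: str) -> np.ndarray:
    arr = np.asarray(rows)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must be a non-empty 2-D binary matrix, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only binary cues 0/1")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class ModelParams:
    """Free parameter of the exemplar model: the mismatch similarity ``s``."""

    s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"s must lie in [0, 1], got {self.s}")


@dataclass(frozen=True)
class ExemplarMemory:
    """Stored exemplars: an ``n x D`` binary cue matrix and ``n`` criteria."""

    cues: np.ndarray
    criteria: np.ndarray

    def __post_init__(self) -> None:
        cues = _as_cue_matrix(self.cues, name="exemplar cues")
        criteria = np.asarray(self.criteria, dtype=float)
        if criteria.ndim != 1 or criteria.shape[0] != cues.shape[0]:
            raise ValueError(
                f"criteria length {criteria.shape} must match number of exemplar rows {cues.shape[0]}"
            )
        if not np.isfinite(criteria).all():
            raise ValueError("all exemplar criteria must be finite")
        object.__setattr__(self, "cues", cues)
        object.__setattr__(self, "criteria", criteria)

    @property
    def n(self) -> int:
        return self.cues.shape[0]

    @property
    def n_cues(self) -> int:
        return self.cues.shape[1]


def mismatch_counts(probes: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between probe rows and exemplar rows.

    Returns an integer matrix of shape ``(n_probes, n_exemplars)``.  This is
    the sufficient statistic of the similarity rule: for binary cues the
    product of per-cue mismatch factors collapses to ``s ** mismatches``.
    """
    probes = _as_cue_matrix(probes, name="probes")
    exemplars = _as_cue_matrix(exemplars, name="exemplars")
    if probes.shape[1] != exemplars.shape[1]:
        raise ValueError(
            f"probe has {probes.shape[1]} cues but exemplar has {exemplars.shape[1]}"
        )
    return (probes[:, None, :] != exemplars[None, :, :]).sum(axis=2)


def similarity(
    probe: Sequence[float] | np.ndarray,
    exemplar: Sequence[float] | np.ndarray,
    params: ModelParams,
) -> float:
    """Context-model similarity ``s ** (D - m)`` between probe and exemplar.

    ``m`` is the number of matching cues.  Identical vectors have similarity
    1 for every ``s``; with ``s = 0`` any mismatch drives it to 0.
    """
    p = as_cue_vector(probe, name="probe")
    e = as_cue_vector(exemplar, name="exemplar")
    if p.shape[0] != e.shape[0]:
        raise ValueError(f"probe has {p.shape[0]} cues but exemplar has {e.shape[0]}")
    mism = int((p != e).sum())
    # 0 ** 0 == 1 is exactly the convention needed for an exact match at s=0.
    return float(params.s**mism)


def _similarity_matrix(mism: np.ndarray, s: float) -> np.ndarray:
    if s == 0.0:
        return (mism == 0).astype(float)
    return np.power(float(s), mism)


def predict_criterion(
    probe: Sequence[float] | np.ndarray,
    memory: ExemplarMemory,
    params: ModelParams,
) -> float:
    """Similarity-weighted average criterion prediction for one probe."""
    return float(predict_batch(np.asarray(probe)[None, :], memory, params)[0])


def predict_batch(
    probes: np.ndarray | Sequence[Sequence[float]],
    memory: ExemplarMemory,
    params: ModelParams,
) -> np.ndarray:
    """Vectorized :func:`predict_criterion` over rows of ``probes``.

    At ``s = 0`` the prediction is the mean criterion over exactly matching
    exemplars (the s -> 0+ limit); a probe with no exact match raises
    :class:`UndefinedPredictionError` naming the offending row.
    """
    mism = mismatch_counts(probes, memory.cues)
    sim = _similarity_matrix(mism, params.s)
    denom = sim.sum(axis=1)
    if np.any(denom == 0.0):
        row = int(np.nonzero(denom == 0.0)[0][0])
        raise UndefinedPredictionError(
            f"prediction undefined for probe row {row}: s={params.s} gives zero "
            "similarity to every stored exemplar (no exact match)"
        )
    return sim @ memory.criteria / denom
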