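"""Synthetic multiple-cue judgment data generator.

Emulates the test phase of a typical multiple-cue judgment experiment on a
0-100 criterion scale: the full stimulus space over ``D`` binary cues, a
linear-additive criterion (intercept plus weighted cue sum, weights summing
to 100), a randomly selected exemplar set that excludes the four most
extreme stimuli, one criterion swap between a pair of exemplars (so the
trained items cannot be reproduced by the additive rule alone), and one
judgment per stimulus.  Responses come from the exemplar model itself at a
known ``s``; each trained exemplar is instead reproduced verbatim (direct
recall of its learned criterion) with probability ``P_r``.  The main
generating regime adds no response noise, so estimation error is entirely
attributable to the model/estimator, not the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ExemplarMemory, ModelParams, predict_batch

__all__ = [
    "SimulationDesign",
    "GenerationRegime",
    "EmpiricalRegimeConfig",
    "Trial",
    "JudgmentDataset",
    "enumerate_stimuli",
    "sample_weights",
    "compute_criteria",
    "build_design",
    "generate_judgments",
    "sample_empirical_regime",
]

SCALE_BOUNDS = (0.0, 100.0)

#: Defaults of the stock design: 5 cues -> 32 stimuli, 12 trained exemplars.
DEFAULT_N_CUES = 5
DEFAULT_N_EXEMPLARS = 12


def enumerate_stimuli(n_cues: int) -> np.ndarray:
    """All ``2**D`` binary cue patterns, lexicographically ordered."""
    if not (1 <= n_cues <= 16):
        raise ValueError(f"number of cues must be in [1, 16], got {n_cues}")
    grid = np.indices((2,) * n_cues).reshape(n_cues, -1).T
    return grid.astype(np.int64)


def sample_weights(n_cues: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``D + 1`` cue weights (intercept first) summing to 100.

    Each weight is drawn i.i.d. from a normal(20, 10) truncated to [0, 100]
    and the vector is rescaled to sum to exactly 100; the marginals are
    therefore only approximately the stated truncated normal.  A degenerate
    all-zero draw (probability ~0) is resampled.
    """
    if n_cues < 1:
        raise ValueError(f"need at least one cue, got {n_cues}")
    a, b = (0.0 - 20.0) / 10.0, (100.0 - 20.0) / 10.0
    while True:
        w = stats.truncnorm.rvs(a, b, loc=20.0, scale=10.0, size=n_cues + 1, random_state=rng)
        if w.sum() > 0:
            return w * (100.0 / w.sum())


def compute_criteria(space: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Linear-additive criterion: intercept plus cue-weighted sum per row."""
    space = np.asarray(space)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or weights.shape[0] != space.shape[1] + 1:
        raise ValueError(
            f"expected {space.shape[1] + 1} weights (intercept + one per cue), got {weights.shape}"
        )
    return weights[0] + space @ weights[1:]


@dataclass(frozen=True)
class SimulationDesign:
    """One sampled stimulus environment: space, criteria, exemplars, swap."""

    space: np.ndarray
    weights: np.ndarray
    criteria: np.ndarray  # post-swap
    exemplar_indices: np.ndarray
    swap_pair: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.exemplar_indices) != len(set(int(i) for i in self.exemplar_indices)):
            raise ValueError("exemplar indices must be distinct")
        lo, hi = SCALE_BOUNDS
        if self.criteria.min() < lo - 1e-9 or self.criteria.max() > hi + 1e-9:
            raise ValueError("criteria must lie on the 0-100 judgment scale")

    @property
    def n_cues(self) -> int:
        return self.space.shape[1]

    @property
    def n_stimuli(self) -> int:
        return self.space.shape[0]

    def exemplar_memory(self) -> ExemplarMemory:
        """The trained exemplars with their learned (post-swap) criteria."""
        idx = np.asarray(self.exemplar_indices)
        return ExemplarMemory(cues=self.space[idx], criteria=self.criteria[idx])

    def to_json(self, path: str | Path, *, seed: Optional[int] = None) -> None:
        payload = {
            "n_cues": self.n_cues,
            "weights": self.weights.tolist(),
            "criteria": self.criteria.tolist(),
            "exemplar_indices": np.asarray(self.exemplar_indices).tolist(),
            "swap_pair": list(self.swap_pair),
            "seed": seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationDesign":
        payload = json.loads(Path(path).read_text())
        space = enumerate_stimuli(payload["n_cues"])
        return cls(
            space=space,
            weights=np.asarray(payload["weights"], dtype=float),
            criteria=np.asarray(payload["criteria"], dtype=float),
            exemplar_indices=np.asarray(payload["exemplar_indices"], dtype=np.int64),
            swap_pair=tuple(payload["swap_pair"]),
        )


def build_design(
    space: np.ndarray,
    criteria: np.ndarray,
    rng: np.random.Generator,
    n_exemplars: int = DEFAULT_N_EXEMPLARS,
    weights: Optional[np.ndarray] = None,
) -> SimulationDesign:
    """Select trained exemplars and apply one criterion swap.

    The two highest- and two lowest-criterion stimuli (ranked before the
    swap) are never selected as exemplars; the swap exchanges the criterion
    values of one uniformly chosen pair of selected exemplars.
    """
    space = np.asarray(space)
    criteria = np.asarray(criteria, dtype=float).copy()
    n_stimuli = space.shape[0]
    if n_exemplars < 2:
        raise ValueError("need at least two exemplars to form a swap pair")
    if n_exemplars > n_stimuli - 4:
        raise ValueError(
            f"cannot select {n_exemplars} exemplars from {n_stimuli} stimuli "
            "after excluding the four criterion extremes"
        )
    order = np.argsort(criteria, kind="stable")
    extremes = set(order[:2].tolist()) | set(order[-2:].tolist())
    eligible = np.array([i for i in range(n_stimuli) if i not in extremes])
    exemplar_indices = np.sort(rng.choice(eligible, size=n_exemplars, replace=False))
    a, b = rng.choice(exemplar_indices, size=2, replace=False)
    criteria[a], criteria[b] = criteria[b], criteria[a]
    if weights is None:
        weights = np.full(space.shape[1] + 1, np.nan)
    return SimulationDesign(
        space=space,
        weights=np.asarray(weights, dtype=float),
        criteria=criteria,
        exemplar_indices=exemplar_indices,
        swap_pair=(int(a), int(b)),
    )


def sample_design(rng: np.random.Generator, n_cues: int = DEFAULT_N_CUES,
                  n_exemplars: int = DEFAULT_N_EXEMPLARS) -> SimulationDesign:
    """Convenience: enumerate the space, draw weights, build a fresh design."""
    space = enumerate_stimuli(n_cues)
    weights = sample_weights(n_cues, rng)
    criteria = compute_criteria(space, weights)
    return build_design(space, criteria, rng, n_exemplars=n_exemplars, weights=weights)


@dataclass(frozen=True)
class GenerationRegime:
    """Generating parameters: true ``s``, recall probability, response noise."""

    s_true: float
    recall_prob: float
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        ModelParams(self.s_true)  # validates [0, 1]
        if not (0.0 <= self.recall_prob <= 1.0):
            raise ValueError(f"recall probability must lie in [0, 1], got {self.recall_prob}")
        if self.noise_sd < 0:
            raise ValueError(f"noise SD must be non-negative, got {self.noise_sd}")


@dataclass(frozen=True)
class Trial:
    probe: np.ndarray
    response: float
    is_trained: bool
    learned_criterion: Optional[float] = None

    def __post_init__(self) -> None:
        if self.is_trained and self.learned_criterion is None:
            raise ValueError("trained trial requires its learned criterion value")
        if not self.is_trained and self.learned_criterion is not None:
            raise ValueError("untrained trial must not carry a learned criterion")
        lo, hi = SCALE_BOUNDS
        if not (lo - 1e-9 <= self.response <= hi + 1e-9):
            raise ValueError(f"response {self.response} outside the {SCALE_BOUNDS} scale")


CSV_COLUMNS = ("response", "is_trained", "learned_criterion")


@dataclass
class JudgmentDataset:
    """Per-trial probes, responses, trained flags and learned criteria."""

    trials: list[Trial]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("dataset must contain at least one trial")
        widths = {t.probe.shape[0] for t in self.trials}
        if len(widths) != 1:
            raise ValueError(f"all trials must share one cue dimension, found {sorted(widths)}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_cues(self) -> int:
        return self.trials[0].probe.shape[0]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(cues, responses, trained mask, learned criteria with NaN holes)."""
        cues = np.stack([t.probe for t in self.trials])
        y = np.array([t.response for t in self.trials])
        trained = np.array([t.is_trained for t in self.trials], dtype=bool)
        learned = np.array(
            [t.learned_criterion if t.is_trained else np.nan for t in self.trials]
        )
        return cues, y, trained, learned

    def to_frame(self) -> pd.DataFrame:
        cues, y, trained, learned = self.arrays()
        frame = pd.DataFrame(cues, columns=[f"cue_{i + 1}" for i in range(self.n_cues)])
        frame["response"] = y
        frame["is_trained"] = trained.astype(int)
        frame["learned_criterion"] = learned
        return frame

    def write_csv(self, path: str | Path) -> None:
        """CSV dialect: ``cue_1..cue_D,response,is_trained,learned_criterion``
        with the last field empty on untrained rows."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: Optional[dict] = None) -> "JudgmentDataset":
        cue_cols = [c for c in frame.columns if c.startswith("cue_")]
        if not cue_cols:
            raise ValueError("no cue_* columns found")
        missing = [c for c in CSV_COLUMNS[:2] if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        trials = []
        for row_number, row in enumerate(frame.itertuples(index=False), start=1):
            record = dict(zip(frame.columns, row))
            probe = np.asarray([record[c] for c in cue_cols])
            if not np.isin(probe, (0, 1)).all():
                raise ValueError(f"row {row_number}: cues must be binary 0/1")
            trained = bool(int(record["is_trained"]))
            learned = record.get("learned_criterion", np.nan)
            learned = None if (learned is None or pd.isna(learned)) else float(learned)
            if trained and learned is None:
                raise ValueError(f"row {row_number}: trained trial missing learned_criterion")
            try:
                trials.append(
                    Trial(
                        probe=probe.astype(np.int64),
                        response=float(record["response"]),
                        is_trained=trained,
                        learned_criterion=learned if trained else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"row {row_number}: {exc}") from exc
        return cls(trials=trials, meta=meta or {})

    @classmethod
    def read_csv(cls, path: str | Path) -> "JudgmentDataset":
        return cls.from_frame(pd.read_csv(path), meta={"source": str(path)})


def generate_judgments(
    design: SimulationDesign,
    regime: GenerationRegime,
    rng: Optional[np.random.Generator] = None,
) -> JudgmentDataset:
    """One judgment per stimulus in the space under the mixture process.

    Untrained probes always get the exemplar-model prediction at the true
    ``s``; each trained probe is independently recalled verbatim (response =
    its learned post-swap criterion) with probability ``P_r`` and judged by
    the model otherwise.  With ``noise_sd > 0`` every response is redrawn
    from a normal centered on that value, truncated to the 0-100 scale.
    """
    if rng is None:
        rng = np.random.default_rng(regime.seed)
    memory = design.exemplar_memory()
    preds = predict_batch(design.space, memory, ModelParams(regime.s_true))
    trained_set = set(int(i) for i in np.asarray(design.exemplar_indices))
    trials = []
    for i in range(design.n_stimuli):
        trained = i in trained_set
        if trained:
            recalled = bool(rng.random() < regime.recall_prob)
            mean = design.criteria[i] if recalled else preds[i]
        else:
            mean = preds[i]
        if regime.noise_sd > 0:
            lo, hi = SCALE_BOUNDS
            a = (lo - mean) / regime.noise_sd
            b = (hi - mean) / regime.noise_sd
            response = float(
                stats.truncnorm.rvs(a, b, loc=mean, scale=regime.noise_sd, random_state=rng)
            )
        else:
            response = float(mean)
        trials.append(
            Trial(
                probe=design.space[i],
                response=response,
                is_trained=trained,
                learned_criterion=float(design.criteria[i]) if trained else None,
            )
        )
    meta = {
        "s_true": regime.s_true,
        "recall_prob": regime.recall_prob,
        "noise_sd": regime.noise_sd,
        "seed": regime.seed,
    }
    return JudgmentDataset(trials=trials, meta=meta)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if var <= 0 or var >= mean * (1.0 - mean):
        raise ValueError(
            f"beta SD {sd} infeasible for mean {mean} (need 0 < SD^2 < mean*(1-mean))"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class EmpiricalRegimeConfig:
    """Beta moments for ``s`` and ``P_r`` plus the noise hyperprior.

    Defaults are method-of-moments matches to the participant-level spread
    reported in published multiple-cue judgment experiments on this
    paradigm: the debiased ``s`` estimates average about .50 (SD .21) and
    recall proportions about .62 (SD .28); per-dataset response noise has
    SD drawn from normal(17, 6) truncated at 0.
    """

    s_mean: float = 0.50
    s_sd: float = 0.21
    pr_mean: float = 0.62
    pr_sd: float = 0.28
    sigma_mean: float = 17.0
    sigma_sd: float = 6.0


def sample_empirical_regime(
    config: EmpiricalRegimeConfig | None = None,
    rng: Optional[np.random.Generator] = None,
) -> GenerationRegime:
    """Draw a noisy, heterogeneous regime: beta ``s`` and ``P_r``, random noise SD."""
    config = config or EmpiricalRegimeConfig()
    if rng is None:
        rng = np.random.default_rng()
    sa, sb = _beta_params(config.s_mean, config.s_sd)
    pa, pb = _beta_params(config.pr_mean, config.pr_sd)
    s_true = float(rng.beta(sa, sb))
    recall_prob = float(rng.beta(pa, pb))
    a = (0.0 - config.sigma_mean) / config.sigma_sd
    sigma = float(
        stats.truncnorm.rvs(a, np.inf, loc=config.sigma_mean, scale=config.sigma_sd,
                            random_state=rng)
    )
    return GenerationRegime(s_true=s_true, recall_prob=recall_prob, noise_sd=sigma)
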