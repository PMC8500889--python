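"""Bayesian estimation of the exemplar model and its latent-mixture extension.

Two likelihoods are fit by MCMC to a test-phase judgment dataset:

* the **original** exemplar model (M0): every response is normal around the
  similarity-weighted prediction, ``y_t ~ Normal(c'_t(s), 1/tau)``;
* the **latent-mixture** extension (M1): untrained probes follow M0's
  likelihood with precision ``tau0``; each trained probe is, with latent
  probability ``phi``, a direct recall of its learned criterion,
  ``y_t ~ Normal(c_t, 1/tau1)``, and otherwise a model-based judgment.
  The reported per-trial recall probabilities are marginal mixture
  responsibilities averaged over the posterior.

Priors: ``s, phi ~ Uniform(0, 1)``; precisions ``~ Gamma(0.001, 0.001)``
(shape, rate) — a standard diffuse precision prior.  All configurable.

The sampler is an adaptive Metropolis-within-Gibbs.  ``s`` is updated by
random-walk Metropolis on the logit scale, with the proposal scale tuned
toward 44% acceptance during a dedicated adaptation phase and frozen
afterwards.  M0's precision has a conjugate Gibbs update.  In the mixture,
the latent recall indicators are instantiated each sweep from their exact
conditionals (data augmentation) so that ``phi`` and both precisions also
get conjugate Gibbs updates — in particular ``tau1`` still mixes perfectly
when no trial is attributed to recall and its posterior collapses to the
diffuse prior.  Convergence is monitored with the split-chain
potential-scale-reduction statistic (R-hat).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datagen import JudgmentDataset
from .density import log_density_at_zero
from .model_core import ExemplarMemory, mismatch_counts

__all__ = [
    "FitConfig",
    "OriginalPosterior",
    "MixturePosterior",
    "fit_original",
    "fit_split",
    "fit_mixture",
    "split_trials",
    "savage_dickey_log_bf",
    "posterior_predictive_rmse",
    "rhat",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk updates


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings and prior hyperparameters.

    The defaults mirror the standard heavyweight schedule used in this
    literature: two chains, 5000 adaptation and 5000 burn-in iterations,
    then 5000 recorded draws per chain thinned by 5 (25,000 sampling
    iterations).  :meth:`desk` returns a lighter schedule suitable for
    simulation studies with many fits; the posteriors here are
    low-dimensional and unimodal, so the shorter schedule changes posterior
    medians well below their Monte-Carlo spread.
    """

    chains: int = 2
    draws_per_chain: int = 5000
    burn_in: int = 5000
    adaptation: int = 5000
    thin: int = 5
    seed: Optional[int] = None
    prior_tau_shape: float = 0.001
    prior_tau_rate: float = 0.001
    rhat_threshold: float = 1.05
    density_method: str = "logspline"

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least two chains are required for R-hat")
        if min(self.draws_per_chain, self.burn_in, self.thin) < 1 or self.adaptation < 0:
            raise ValueError("draws, burn-in and thin must be positive")

    @classmethod
    def desk(cls, seed: Optional[int] = None, **overrides) -> "FitConfig":
        """Light schedule for large simulation grids.

        Keeps the pooled posterior sample size at the heavyweight
        schedule's 10,000 draws (the Savage-Dickey boundary-density
        estimate depends on it) but shortens adaptation/burn-in and thins
        less, cutting sampling iterations per chain from 35,000 to 12,000.
        """
        base = dict(draws_per_chain=5000, burn_in=1000, adaptation=1000, thin=2, seed=seed)
        base.update(overrides)
        return cls(**base)


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (m, n).  Each chain is split in half, and the
    classic between/within variance ratio is computed on the 2m half
    chains; values near 1 indicate convergence.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two chains")
    if arr.shape[1] < 4:
        raise ValueError("chains too short to split for R-hat")
    half = arr.shape[1] // 2
    splits = np.vstack([arr[:, :half], arr[:, half : 2 * half]])
    n = splits.shape[1]
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _logit_prior(zeta: float) -> float:
    # log density (up to a constant) of a Uniform(0,1) variable on the logit scale
    p = expit(zeta)
    return float(np.log(p) + np.log1p(-p))


class _BlockSampler:
    """One adaptive random-walk Metropolis block on an unbounded scale."""

    __slots__ = ("value", "scale", "accepted", "proposed")

    def __init__(self, value: float, scale: float = 0.5):
        self.value = value
        self.scale = scale
        self.accepted = 0
        self.proposed = 0

    def adapt(self) -> None:
        if self.proposed == 0:
            return
        rate = self.accepted / self.proposed
        self.scale *= float(np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5)))
        self.scale = float(np.clip(self.scale, 1e-6, 50.0))
        self.accepted = 0
        self.proposed = 0


@dataclass
class _PosteriorBase:
    config: FitConfig
    rhats: dict = field(default_factory=dict)
    n_trials: int = 0

    @property
    def converged(self) -> bool:
        return all(v < self.config.rhat_threshold for v in self.rhats.values())

    def _params(self) -> dict:
        raise NotImplementedError

    def pooled(self, name: str) -> np.ndarray:
        return self._params()[name].ravel()

    def median(self, name: str) -> float:
        return float(np.median(self.pooled(name)))

    def mean(self, name: str) -> float:
        return float(np.mean(self.pooled(name)))

    def summary(self) -> dict:
        out = {"model": self.model, "converged": self.converged, "n_trials": self.n_trials}
        for name in self._params():
            out[name] = {
                "median": self.median(name),
                "mean": self.mean(name),
                "sd": float(np.std(self.pooled(name), ddof=1)),
                "rhat": self.rhats.get(name),
            }
        return out

    def to_csv(self, path: str | Path) -> None:
        """Long-format draws: ``chain,draw,parameter,value``."""
        rows = []
        for name, arr in self._params().items():
            m, n = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(m), n),
                        "draw": np.tile(np.arange(n), m),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


@dataclass
class OriginalPosterior(_PosteriorBase):
    """Posterior samples of (s, tau) under the original exemplar model."""

    s: np.ndarray = None
    tau: np.ndarray = None
    model: str = "M0"
    # retained for posterior predictive simulation
    _pred_cache: Optional[tuple] = None

    def _params(self) -> dict:
        return {"s": self.s, "tau": self.tau}

    @property
    def s_hat(self) -> float:
        return self.median("s")


@dataclass
class MixturePosterior(_PosteriorBase):
    """Posterior samples of (s, phi, tau0, tau1) under the latent mixture."""

    s: np.ndarray = None
    phi: np.ndarray = None
    tau0: np.ndarray = None
    tau1: np.ndarray = None
    recall_probabilities: np.ndarray = None  # per trial; NaN for untrained
    model: str = "M1"
    _pred_cache: Optional[tuple] = None

    def _params(self) -> dict:
        return {"s": self.s, "phi": self.phi, "tau0": self.tau0, "tau1": self.tau1}

    @property
    def s_hat(self) -> float:
        return self.median("s")

    @property
    def phi_hat(self) -> float:
        return self.median("phi")


def _memory_from_data(data: JudgmentDataset) -> ExemplarMemory:
    cues, _, trained, learned = data.arrays()
    if not trained.any():
        raise ValueError("dataset contains no trained trials to form exemplar memory")
    return ExemplarMemory(cues=cues[trained], criteria=learned[trained])


def _prediction_closure(cues: np.ndarray, memory: ExemplarMemory):
    """Fast per-s predictions via the cached mismatch-count matrix."""
    M = mismatch_counts(cues, memory.cues).astype(float)
    c = memory.criteria

    def predict(s: float) -> np.ndarray:
        S = np.exp(M * np.log(s)) if s > 0 else (M == 0).astype(float)
        denom = S.sum(axis=1)
        return (S @ c) / denom

    return predict


def _chain_seeds(config: FitConfig) -> list[np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(s) for s in root.spawn(config.chains)]


def fit_original(
    data: JudgmentDataset,
    config: Optional[FitConfig] = None,
    memory: Optional[ExemplarMemory] = None,
) -> OriginalPosterior:
    """MCMC fit of the original exemplar model to *all* trials.

    ``memory`` defaults to the trained exemplars carried by the dataset
    itself (cues + learned criteria); pass it explicitly when fitting a
    subset that lacks trained trials.
    """
    config = config or FitConfig()
    cues, y, _, _ = data.arrays()
    memory = memory or _memory_from_data(data)
    predict = _prediction_closure(cues, memory)
    n = y.size
    a0, b0 = config.prior_tau_shape, config.prior_tau_rate

    def ss(s: float) -> float:
        r = y - predict(s)
        return float(r @ r)

    total = config.adaptation + config.burn_in + config.draws_per_chain * config.thin
    keep_from = config.adaptation + config.burn_in
    s_draws = np.empty((config.chains, config.draws_per_chain))
    tau_draws = np.empty_like(s_draws)

    for ci, rng in enumerate(_chain_seeds(config)):
        zeta = float(logit(rng.uniform(0.05, 0.95)))
        block = _BlockSampler(zeta, scale=0.5)
        ss_cur = ss(expit(block.value))
        kept = 0
        for it in range(total):
            tau = rng.gamma(a0 + n / 2.0, 1.0 / (b0 + ss_cur / 2.0))
            prop = block.value + block.scale * rng.standard_normal()
            ss_prop = ss(float(expit(prop)))
            log_acc = (
                -tau / 2.0 * (ss_prop - ss_cur)
                + _logit_prior(prop)
                - _logit_prior(block.value)
            )
            block.proposed += 1
            if np.log(rng.random()) < log_acc:
                block.value = prop
                ss_cur = ss_prop
                block.accepted += 1
            if it < config.adaptation and (it + 1) % 50 == 0:
                block.adapt()
            if it >= keep_from and (it - keep_from) % config.thin == 0:
                s_draws[ci, kept] = expit(block.value)
                tau_draws[ci, kept] = tau
                kept += 1

    post = OriginalPosterior(
        config=config,
        s=s_draws,
        tau=tau_draws,
        n_trials=n,
        _pred_cache=(cues, memory),
    )
    post.rhats = {"s": rhat(s_draws), "tau": rhat(np.log(tau_draws))}
    return post


def split_trials(
    data: JudgmentDataset, tol: float = 1e-9
) -> tuple[Optional[JudgmentDataset], Optional[JudgmentDataset]]:
    """Partition into (recalled exemplars, everything else).

    A trained trial counts as a correct recall when its response is within
    ``tol`` of its learned criterion; untrained trials always go to the
    remainder.  Either part may be ``None`` when empty.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    recalled, remainder = [], []
    for t in data.trials:
        if t.is_trained and abs(t.response - t.learned_criterion) <= tol:
            recalled.append(t)
        else:
            remainder.append(t)
    make = lambda ts: JudgmentDataset(trials=ts, meta=dict(data.meta)) if ts else None
    return make(recalled), make(remainder)


def fit_split(
    data: JudgmentDataset,
    config: Optional[FitConfig] = None,
    tol: float = 1e-9,
) -> OriginalPosterior:
    """Original-model fit restricted to the subset without correct recalls.

    The exemplar memory still consists of *all* trained exemplars of the
    full dataset; only the likelihood is restricted to the non-recalled
    trials and new stimuli.
    """
    _, remainder = split_trials(data, tol=tol)
    if remainder is None:
        raise ValueError("split left no trials to fit: every trial is a correct recall")
    memory = _memory_from_data(data)
    post = fit_original(remainder, config=config, memory=memory)
    post.model = "M0_split"
    return post


def fit_mixture(
    data: JudgmentDataset,
    config: Optional[FitConfig] = None,
    memory: Optional[ExemplarMemory] = None,
) -> MixturePosterior:
    """MCMC fit of the latent-mixture (judgment vs. direct recall) model."""
    config = config or FitConfig()
    cues, y, trained, learned = data.arrays()
    if not trained.any():
        if memory is None:
            raise ValueError(
                "mixture model needs trained trials (or an explicit exemplar memory)"
            )
        warnings.warn(
            "dataset has no trained trials: phi is unidentified and its "
            "posterior is prior-dominated",
            stacklevel=2,
        )
    memory = memory or _memory_from_data(data)
    predict = _prediction_closure(cues, memory)
    r1_trained = (y[trained] - learned[trained]) ** 2
    a0, b0 = config.prior_tau_shape, config.prior_tau_rate
    n_trained = int(trained.sum())

    def residuals0(s: float) -> tuple[np.ndarray, np.ndarray]:
        r = (y - predict(s)) ** 2
        return r[~trained], r[trained]

    total = config.adaptation + config.burn_in + config.draws_per_chain * config.thin
    keep_from = config.adaptation + config.burn_in
    shape = (config.chains, config.draws_per_chain)
    s_draws = np.empty(shape)
    phi_draws = np.empty(shape)
    tau0_draws = np.empty(shape)
    tau1_draws = np.empty(shape)
    resp_sum = np.zeros(n_trained)

    def responsibilities(phi, tau0, tau1, r0t):
        # P(z_t = 1 | params) per trained trial
        la = np.log(phi) + 0.5 * (np.log(tau1) - _LOG_2PI) - tau1 / 2.0 * r1_trained
        lb = np.log1p(-phi) + 0.5 * (np.log(tau0) - _LOG_2PI) - tau0 / 2.0 * r0t
        return np.exp(la - np.logaddexp(la, lb))

    for ci, rng in enumerate(_chain_seeds(config)):
        s_block = _BlockSampler(float(logit(rng.uniform(0.05, 0.95))), scale=0.5)
        s_cur = float(expit(s_block.value))
        r0u, r0t = residuals0(s_cur)
        tau0 = 1.0 / max(float(np.mean(np.concatenate([r0u, r0t]))), 1e-3)
        tau1 = 1.0 / max(float(np.mean(r1_trained)), 1e-3) if r1_trained.size else 1.0
        phi_cur = float(rng.uniform(0.05, 0.95))
        kept = 0
        for it in range(total):
            # --- recall indicators z (data augmentation; restores conjugacy) ---
            if n_trained:
                p1 = responsibilities(phi_cur, tau0, tau1, r0t)
                z = rng.random(n_trained) < p1
            else:
                z = np.zeros(0, dtype=bool)
            k = int(z.sum())
            # --- phi | z  (Uniform(0,1) = Beta(1,1) prior) ---
            phi_cur = float(rng.beta(1 + k, 1 + n_trained - k))
            # --- tau0, tau1 | z (conjugate Gamma updates) ---
            ss0 = float(r0u.sum() + r0t[~z].sum())
            m0 = r0u.size + n_trained - k
            tau0 = rng.gamma(a0 + m0 / 2.0, 1.0 / (b0 + ss0 / 2.0))
            ss1 = float(r1_trained[z].sum())
            # unidentified when k = 0: this draw then comes from the diffuse
            # prior; floor it so log(tau1) stays finite under underflow
            tau1 = max(rng.gamma(a0 + k / 2.0, 1.0 / (b0 + ss1 / 2.0)), 1e-290)
            # --- s | z, tau0 (random-walk Metropolis on the logit scale) ---
            prop = s_block.value + s_block.scale * rng.standard_normal()
            r0u_p, r0t_p = residuals0(float(expit(prop)))
            ss0_p = float(r0u_p.sum() + r0t_p[~z].sum())
            log_acc = (
                -tau0 / 2.0 * (ss0_p - ss0)
                + _logit_prior(prop)
                - _logit_prior(s_block.value)
            )
            s_block.proposed += 1
            if np.log(rng.random()) < log_acc:
                s_block.value, r0u, r0t = prop, r0u_p, r0t_p
                s_block.accepted += 1

            if it < config.adaptation and (it + 1) % 50 == 0:
                s_block.adapt()
            if it >= keep_from and (it - keep_from) % config.thin == 0:
                s_draws[ci, kept] = expit(s_block.value)
                phi_draws[ci, kept] = phi_cur
                tau0_draws[ci, kept] = tau0
                tau1_draws[ci, kept] = tau1
                if n_trained:
                    resp_sum += responsibilities(phi_cur, tau0, tau1, r0t)
                kept += 1

    recall_probs = np.full(y.size, np.nan)
    recall_probs[trained] = resp_sum / (config.chains * config.draws_per_chain)
    post = MixturePosterior(
        config=config,
        s=s_draws,
        phi=phi_draws,
        tau0=tau0_draws,
        tau1=tau1_draws,
        recall_probabilities=recall_probs,
        n_trials=y.size,
        _pred_cache=(cues, memory, trained, learned),
    )
    post.rhats = {
        "s": rhat(s_draws),
        "phi": rhat(phi_draws),
        "tau0": rhat(np.log(tau0_draws)),
        "tau1": rhat(np.log(tau1_draws)),
    }
    return post


def savage_dickey_log_bf(
    mixture_post: MixturePosterior,
    prior_density_at_zero: float = 1.0,
    method: Optional[str] = None,
) -> float:
    """Savage-Dickey log Bayes factor for the mixture over the original model.

    The original model is nested in the mixture at ``phi = 0``, so
    ``BF_10 = p(phi=0 | M1) / p(phi=0 | data, M1)``: the prior density at 0
    (exactly 1 under the Uniform(0,1) prior) over the posterior density at
    0, estimated from the pooled phi samples with a boundary-capable
    estimator.  Positive values favour the mixture.
    """
    method = method or mixture_post.config.density_method
    samples = mixture_post.pooled("phi")
    log_post = log_density_at_zero(samples, method=method)
    return float(np.log(prior_density_at_zero) - log_post)


def posterior_predictive_rmse(
    post: Union[OriginalPosterior, MixturePosterior],
    data: JudgmentDataset,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """RMSE between responses and per-trial posterior-predictive medians.

    One replicate response is simulated per trial and recorded posterior
    draw; the per-trial median over replicates is then compared with the
    observed response.
    """
    if rng is None:
        seed = post.config.seed
        rng = np.random.default_rng(None if seed is None else seed + 99991)
    cues, y, trained, learned = data.arrays()
    s = post.pooled("s")
    # predictions per draw: (draws, trials)
    memory = post._pred_cache[1]
    M = mismatch_counts(cues, memory.cues).astype(float)
    S = np.exp(np.log(s)[:, None, None] * M[None, :, :])
    preds = (S @ memory.criteria) / S.sum(axis=2)
    if isinstance(post, MixturePosterior):
        tau0 = post.pooled("tau0")[:, None]
        reps = preds + rng.standard_normal(preds.shape) / np.sqrt(tau0)
        idx = np.where(trained)[0]
        if idx.size:
            phi = post.pooled("phi")[:, None]
            tau1 = post.pooled("tau1")[:, None]
            c_t = learned[idx][None, :]
            # replicate each trained trial from its *per-trial* posterior
            # recall state: P(z_t=1 | params, y_t), not the marginal phi —
            # an exactly recalled trial's predictive must sit on c_t
            la = np.log(phi) + 0.5 * (np.log(tau1) - _LOG_2PI) - tau1 / 2.0 * (y[idx] - c_t) ** 2
            lb = (
                np.log1p(-phi)
                + 0.5 * (np.log(tau0) - _LOG_2PI)
                - tau0 / 2.0 * (y[idx][None, :] - preds[:, idx]) ** 2
            )
            p_recall = np.exp(la - np.logaddexp(la, lb))
            recall_reps = c_t + rng.standard_normal((preds.shape[0], idx.size)) / np.sqrt(tau1)
            pick = rng.random((preds.shape[0], idx.size)) < p_recall
            reps[:, idx] = np.where(pick, recall_reps, reps[:, idx])
    else:
        sd = 1.0 / np.sqrt(post.pooled("tau"))[:, None]
        reps = preds + sd * rng.standard_normal(preds.shape)
    medians = np.median(reps, axis=0)
    return float(np.sqrt(np.mean((y - medians) ** 2)))


def write_summary(
    path: str | Path,
    post: Union[OriginalPosterior, MixturePosterior],
    extras: Optional[dict] = None,
) -> None:
    """Summary JSON: medians/means/SDs, R-hat, config echo, optional extras."""
    payload = post.summary()
    payload["config"] = dataclasses.asdict(post.config)
    if extras:
        payload.update(extras)
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
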