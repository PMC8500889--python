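"""Bayesian estimation: original model, split estimator, latent mixture."""

import dataclasses

import numpy as np
import pytest

from exemplarmix import (
    FitConfig,
    GenerationRegime,
    JudgmentDataset,
    MixturePosterior,
    Trial,
    fit_mixture,
    fit_original,
    fit_split,
    generate_judgments,
    posterior_predictive_rmse,
    rhat,
    sample_design,
    savage_dickey_log_bf,
    split_trials,
)
from exemplarmix.model_core import mismatch_counts


def grid_search_ml(dataset, grid=None):
    """Independent maximum-likelihood oracle: brute-force minimization of the
    residual sum of squares over a fine s grid."""
    cues, y, trained, learned = dataset.arrays()
    mem_cues, mem_c = cues[trained], learned[trained]
    M = mismatch_counts(cues, mem_cues).astype(float)
    grid = np.linspace(1e-4, 1.0, 2001) if grid is None else grid
    best_ss, best_s = np.inf, None
    for s in grid:
        S = np.exp(M * np.log(s))
        pred = (S @ mem_c) / S.sum(axis=1)
        ss = float(((y - pred) ** 2).sum())
        if ss < best_ss:
            best_ss, best_s = ss, s
    return best_s


class TestRhat:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 4000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert rhat(chains) > 3.0

    def test_matches_hand_computed_split_chain_formula(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 20)) + np.array([[0.0], [1.0]])
        # independent oracle: split each chain in half, classic B/W formula
        splits = np.vstack([chains[:, :10], chains[:, 10:]])
        n = 10
        W = splits.var(axis=1, ddof=1).mean()
        B = n * splits.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(chains) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_arviz_split_rhat(self):
        import arviz as az

        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 600)) + rng.normal(0, 0.2, size=(3, 1))
        theirs = float(az.rhat(chains, method="split"))
        assert rhat(chains) == pytest.approx(theirs, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="two chains"):
            rhat(np.zeros((1, 100)))


class TestSplitTrials:
    def test_perfect_recall_dataset_splits_at_exemplar_count(self, dataset_factory):
        _, ds = dataset_factory(s_true=0.8, recall_prob=1.0, seed=31)
        recalled, remainder = split_trials(ds, tol=1e-9)
        assert len(recalled) == 12 and len(remainder) == 20
        assert not any(t.is_trained for t in remainder.trials)

    def test_no_recall_dataset_has_empty_recalled_part(self, dataset_factory):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.0, seed=32)
        recalled, remainder = split_trials(ds)
        assert recalled is None and len(remainder) == 32

    def test_infinite_tolerance_classifies_all_trained_as_recalled(self, dataset_factory):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.0, seed=33)
        recalled, remainder = split_trials(ds, tol=np.inf)
        assert len(recalled) == 12 and len(remainder) == 20

    def test_parts_partition_the_data(self, dataset_factory):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.5, seed=34)
        recalled, remainder = split_trials(ds)
        n_rec = 0 if recalled is None else len(recalled)
        assert n_rec + len(remainder) == len(ds)


class TestFitOriginal:
    def test_recovers_s_on_no_recall_data(self, dataset_factory, tiny_fit_config):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.0, seed=41)
        post = fit_original(ds, tiny_fit_config)
        assert post.s_hat == pytest.approx(0.300, abs=0.01)
        assert post.converged
        assert (post.pooled("s") >= 0).all() and (post.pooled("s") <= 1).all()
        assert (post.pooled("tau") > 0).all()

    def test_posterior_median_tracks_ml_oracle_on_mixed_data(
        self, dataset_factory, tiny_fit_config
    ):
        """On recall-contaminated data the Bayesian point estimate must sit at
        the likelihood optimum found by an independent grid search."""
        _, ds = dataset_factory(s_true=0.8, recall_prob=1.0, seed=42)
        post = fit_original(ds, tiny_fit_config)
        assert post.s_hat < 0.8  # downward bias
        assert post.s_hat == pytest.approx(grid_search_ml(ds), abs=0.04)

    def test_split_equals_original_on_no_recall_data(self, dataset_factory, tiny_fit_config):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.0, seed=43)
        orig = fit_original(ds, tiny_fit_config)
        split = fit_split(ds, tiny_fit_config)
        assert split.n_trials == orig.n_trials
        assert split.s_hat == pytest.approx(orig.s_hat, abs=0.01)

    def test_split_unbiased_on_perfect_recall_data(self, dataset_factory, tiny_fit_config):
        _, ds = dataset_factory(s_true=0.8, recall_prob=1.0, seed=44)
        post = fit_split(ds, tiny_fit_config)
        assert post.n_trials == 20
        assert post.s_hat == pytest.approx(0.800, abs=0.005)

    def test_seeded_fit_is_reproducible(self, dataset_factory, tiny_fit_config):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.5, seed=45)
        a = fit_original(ds, tiny_fit_config)
        b = fit_original(ds, tiny_fit_config)
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_array_equal(a.tau, b.tau)


class TestFitMixture:
    def test_unbiased_s_and_phi_near_one_on_perfect_recall(
        self, dataset_factory, tiny_fit_config
    ):
        _, ds = dataset_factory(s_true=0.8, recall_prob=1.0, seed=51)
        post = fit_mixture(ds, tiny_fit_config)
        assert post.s_hat == pytest.approx(0.800, abs=0.005)
        # phi posterior is ~Beta(13, 1) when all 12 trained trials are
        # certain recalls; its median is 0.5**(1/13) ~ .948
        assert post.phi_hat == pytest.approx(0.948, abs=0.04)
        trained_probs = post.recall_probabilities[~np.isnan(post.recall_probabilities)]
        assert (trained_probs > 0.95).all()
        assert post.converged

    def test_recall_probabilities_separate_recalled_trials(
        self, dataset_factory, tiny_fit_config
    ):
        _, ds = dataset_factory(s_true=0.8, recall_prob=0.5, seed=52)
        post = fit_mixture(ds, tiny_fit_config)
        _, y, trained, learned = ds.arrays()
        exact = np.isclose(y, np.where(np.isnan(learned), np.inf, learned))
        probs = post.recall_probabilities
        assert np.nanmin(probs[exact & trained]) > 0.9
        assert np.nanmax(probs[trained & ~exact]) < 0.1

    def test_dataset_without_trained_trials_needs_memory(self, dataset_factory):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.0, seed=53)
        untrained_only = JudgmentDataset(
            trials=[t for t in ds.trials if not t.is_trained]
        )
        with pytest.raises(ValueError, match="trained"):
            fit_mixture(untrained_only)

    def test_prior_dominated_phi_with_external_memory(self, dataset_factory):
        design, ds = dataset_factory(s_true=0.3, recall_prob=0.0, seed=54)
        untrained_only = JudgmentDataset(trials=[t for t in ds.trials if not t.is_trained])
        cfg = FitConfig(chains=2, draws_per_chain=300, burn_in=100, adaptation=200, thin=1, seed=5)
        with pytest.warns(UserWarning, match="unidentified"):
            post = fit_mixture(untrained_only, cfg, memory=design.exemplar_memory())
        # no trained trials: phi posterior is its Uniform(0, 1) prior
        assert post.phi_hat == pytest.approx(0.5, abs=0.1)


class TestSavageDickey:
    def _stub(self, phi_samples, method="logspline"):
        cfg = FitConfig(seed=0, density_method=method)
        arr = np.asarray(phi_samples).reshape(2, -1)
        return MixturePosterior(
            config=cfg, s=arr, phi=arr, tau0=np.ones_like(arr), tau1=np.ones_like(arr)
        )

    def test_posterior_equal_to_prior_gives_log_bf_zero(self):
        rng = np.random.default_rng(6)
        post = self._stub(rng.uniform(size=8000))
        assert savage_dickey_log_bf(post) == pytest.approx(0.0, abs=0.4)

    def test_boundary_density_translates_to_bayes_factor(self):
        # phi ~ Beta(1,10): posterior density 10 at zero -> BF_10 = 1/10
        rng = np.random.default_rng(7)
        post = self._stub(rng.beta(1, 10, 8000))
        assert savage_dickey_log_bf(post) == pytest.approx(-np.log(10.0), abs=0.4)

    def test_vanishing_boundary_mass_strongly_favours_mixture(self):
        rng = np.random.default_rng(8)
        post = self._stub(rng.beta(2, 1, 8000))
        assert savage_dickey_log_bf(post) > 1.5

    def test_degenerate_phi_samples_rejected(self):
        post = self._stub(np.full(2000, 0.7))
        with pytest.raises(ValueError, match="degenerate"):
            savage_dickey_log_bf(post)


class TestPosteriorPredictiveRmse:
    def test_near_zero_when_posterior_concentrates_on_truth(
        self, dataset_factory, tiny_fit_config
    ):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.0, seed=61)
        post = fit_original(ds, tiny_fit_config)
        # zero-noise, no-recall data: the fitted model reproduces every trial
        assert posterior_predictive_rmse(post, ds) < 0.2

    def test_mixture_beats_original_on_recall_contaminated_data(
        self, dataset_factory, tiny_fit_config
    ):
        _, ds = dataset_factory(s_true=0.8, recall_prob=1.0, seed=62)
        rmse_orig = posterior_predictive_rmse(fit_original(ds, tiny_fit_config), ds)
        rmse_mix = posterior_predictive_rmse(fit_mixture(ds, tiny_fit_config), ds)
        assert rmse_mix < 0.2 < rmse_orig

    def test_rmse_is_seeded_and_reproducible(self, dataset_factory, tiny_fit_config):
        _, ds = dataset_factory(s_true=0.3, recall_prob=0.5, seed=63)
        post = fit_original(ds, tiny_fit_config)
        r1 = posterior_predictive_rmse(post, ds, rng=np.random.default_rng(9))
        r2 = posterior_predictive_rmse(post, ds, rng=np.random.default_rng(9))
        assert r1 == r2


class TestExports:
    def test_posterior_csv_and_summary(self, dataset_factory, tiny_fit_config, tmp_path):
        import json
        import pandas as pd
        from exemplarmix.bayes_fit import write_summary

        _, ds = dataset_factory(s_true=0.3, recall_prob=0.5, seed=71)
        post = fit_original(ds, tiny_fit_config)
        csv_path = tmp_path / "draws.csv"
        post.to_csv(csv_path)
        frame = pd.read_csv(csv_path)
        assert list(frame.columns) == ["chain", "draw", "parameter", "value"]
        assert set(frame["parameter"]) == {"s", "tau"}
        assert len(frame) == 2 * tiny_fit_config.draws_per_chain * 2

        json_path = tmp_path / "summary.json"
        write_summary(json_path, post, extras={"note": 1})
        payload = json.loads(json_path.read_text())
        assert payload["model"] == "M0"
        assert 0 <= payload["s"]["median"] <= 1
        assert payload["config"]["seed"] == tiny_fit_config.seed
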