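# exemplarmix

Exemplar-based multiple-cue judgment modeling with an explicit
direct-recall process: simulation, Bayesian estimation, and a
parameter-recovery study of the similarity parameter's estimation bias.

## The problem

In multiple-cue judgment experiments, participants learn a set of training
stimuli ("exemplars") with feedback about a continuous criterion (a 0–100
scale), then judge both trained and new stimuli.  The standard analysis
fits the context model extended to a continuous criterion: stimuli are
vectors of *D* binary cues, the similarity between a probe **p** and a
stored exemplar **e**ⱼ is

S(**p**, **e**ⱼ) = s^(D−m),

where *m* is the number of matching cues and *s* ∈ [0, 1] is the
similarity (or attention / memory-discriminability) parameter, and the
judged criterion is the similarity-weighted average of the stored criteria

c′(**p**) = Σⱼ S(**p**, **e**ⱼ) · c(**e**ⱼ) / Σⱼ S(**p**, **e**ⱼ).

The psychological catch: after extensive training, a participant shown a
trained exemplar often does not *judge* it at all — they simply recall its
learned criterion verbatim.  The exemplar model can only mimic verbatim
reproduction by driving *s* toward 0, so mixing recalled and judged trials
in one fit biases the estimated *s* downward, severely so when memory is
good.  This package implements that demonstration end to end:

* **model_core** — the deterministic similarity and prediction math;
* **datagen** — a synthetic test-phase generator (full 2^D stimulus space,
  linear-additive criteria from truncated-normal cue weights summing to
  100, 12 trained exemplars excluding the four criterion extremes, one
  criterion swap, and responses that are model judgments except that each
  trained exemplar is recalled verbatim with probability *P*ᵣ);
* **bayes_fit** — MCMC estimation of the original model
  (y ~ Normal(c′(s), 1/τ), s ~ Uniform(0,1), τ ~ Gamma(.001, .001)), of
  the *split* estimator (the same model restricted to trials that are not
  exact recalls), and of a latent-mixture extension in which each trained
  trial is a direct recall (y ~ Normal(cₜ, 1/τ₁)) with latent probability
  ϕ and a model-based judgment otherwise; plus Savage–Dickey log Bayes
  factors BF₁₀ = p(ϕ=0)/p(ϕ=0 | data) and posterior-predictive RMSE;
* **recovery** — the Monte-Carlo recovery study over a grid of true *s*
  and recall probability *P*ᵣ, with per-replication seeding;
* **interface** — a thin CLI (`simulate`, `fit`, `recover`, `report`).

## Worked example

`python examples/simulate_and_fit.py` generates one dataset at s = .8 with
perfect recall (*P*ᵣ = 1) and fits all three estimators:

```
32 trials, 12 trained exemplars, generating s = 0.8, recall probability = 1.0
  s_orig  (all trials)          = 0.359   R-hat 1.000
  s_split (non-recalled subset) = 0.800   R-hat 1.000
  s_int   (latent mixture)      = 0.800   phi_hat = 0.949
the original estimate is biased toward 0; the split and mixture estimates are not
```

The conventional estimate (`s_orig`) collapses to less than half the
generating value because 12 of 32 responses are verbatim recalls; the
split-data estimator and the latent-mixture model both recover .800
exactly on noise-free data.  `examples/recovery_cell.py` repeats this over
ten fresh designs (mean s_orig = 0.227, mean s_int = 0.800, mean log
BF₁₀ = 17.7 in favour of the mixture), `examples/model_comparison.py`
shows the Bayes factor and predictive-RMSE comparison on a partially
recalled dataset, and `examples/empirical_regime.py` simulates a noisy,
heterogeneous participant with beta-distributed *s* and *P*ᵣ.

## Command line

```bash
exemplarmix simulate --d 5 --s .3 --pr .5 --seed 1 --out data.csv
exemplarmix fit data.csv --model mixture
exemplarmix recover --s-grid .001,.1,.3,.8 --pr-grid .1,.5,1 --reps 30 --seed 1 --out results/
```

`recover` writes three CSV tables (estimator means/SDs, log Bayes
factors, predictive RMSE per model, each laid out estimator × *P*ᵣ rows by
true-*s* columns) and a machine-readable `cells.json`.

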