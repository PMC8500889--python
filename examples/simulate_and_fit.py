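"""Generate one judgment dataset with perfect recall and fit all three ways.

The data are generated from the exemplar model at s = .8 over the full
5-cue stimulus space (32 trials, 12 trained exemplars), except that every
trained exemplar's criterion is reproduced verbatim (recall probability 1).
Fitting the original model to all trials drags the similarity estimate far
below .8; restricting the fit to the non-recalled trials (split estimator)
or modeling recall explicitly (latent mixture) recovers the truth.
"""

import numpy as np

from exemplarmix import (
    FitConfig,
    GenerationRegime,
    fit_mixture,
    fit_original,
    fit_split,
    generate_judgments,
    sample_design,
)

rng = np.random.default_rng(0)
design = sample_design(rng)  # fresh weights, criteria, exemplars, one swap
regime = GenerationRegime(s_true=0.8, recall_prob=1.0, noise_sd=0.0)
data = generate_judgments(design, regime, rng)
print(f"{len(data)} trials, {sum(t.is_trained for t in data.trials)} trained exemplars, "
      f"generating s = {regime.s_true}, recall probability = {regime.recall_prob}")

config = FitConfig.desk(seed=1)
orig = fit_original(data, config)
split = fit_split(data, config)
mix = fit_mixture(data, config)

print(f"  s_orig  (all trials)          = {orig.s_hat:.3f}   R-hat {max(orig.rhats.values()):.3f}")
print(f"  s_split (non-recalled subset) = {split.s_hat:.3f}   R-hat {max(split.rhats.values()):.3f}")
print(f"  s_int   (latent mixture)      = {mix.s_hat:.3f}   phi_hat = {mix.phi_hat:.3f}")
print("the original estimate is biased toward 0; the split and mixture estimates are not")
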