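# Methods

## Model

Stimuli are vectors of D binary cues.  Similarity between a probe and a
stored exemplar follows the context model's multiplicative rule: each
matching cue contributes a factor 1 and each mismatching cue a factor
s ∈ [0, 1], so S = s^(D−m) with m matching cues.  The judged criterion of
a probe is the similarity-weighted average of the stored exemplar criteria
(a convex combination, hence always inside the range of stored criteria).
Limits: at s = 1 every probe is predicted as the plain mean of the stored
criteria; as s → 0 the prediction converges to the mean criterion of
exactly matching exemplars.  We define the s = 0 case by that limit and
raise an explicit error when no exact match exists (the weighted average
is 0/0 there).  Similarities are computed in linear space — with D ≤ 10
and s ≥ .001, s^D cannot underflow meaningfully — while all likelihood
computation is done in log space.  Cues are strictly binary; continuous
cue dimensions are out of scope.

Two observation models are fit to a test-phase dataset (one response per
stimulus, a trained flag, and the learned criterion c_t for trained
trials):

* **Original exemplar model (M0).**  Every response is
  y_t ~ Normal(c′_t(s), 1/τ).  Because verbatim reproductions of trained
  criteria can only be mimicked by s → 0, this model's s estimate is
  biased downward when direct recall occurs.
* **Latent-mixture extension (M1).**  Untrained trials follow M0's
  likelihood with precision τ₀.  Each trained trial carries a latent
  indicator z_t ~ Bernoulli(ϕ): with z_t = 1 the response is a direct
  recall, y_t ~ Normal(c_t, 1/τ₁); with z_t = 0 it is a model-based
  judgment.  ϕ is the latent memory probability.

A third estimator, the **split** estimator, refits M0 on the subset of
trials that are not exact recalls (|y_t − c_t| > tol; tol defaults to
1e−9 for noise-free data and must be chosen by the analyst for noisy
data).  The exemplar memory always remains the full trained set; only the
likelihood is restricted.

## Priors and estimation

s, ϕ ~ Uniform(0, 1); τ, τ₀, τ₁ ~ Gamma(0.001, 0.001) (shape/rate), the
conventional diffuse precision prior in general-purpose Bayesian tooling.
All are configurable through `FitConfig`.  Point estimates are posterior
medians (posterior means are also reported); the reference MCMC schedule
is two chains × 5000 recorded draws after 5000 adaptation and 5000
burn-in iterations with thinning 5.

The sampler is an adaptive Metropolis-within-Gibbs scheme.  s is updated
by a random-walk Metropolis step on the logit scale, its proposal scale
tuned toward 44% acceptance in batches of 50 during the adaptation phase
and frozen afterwards.  In M0, τ has a conjugate Gamma update.  In M1 the
indicators z_t are instantiated every sweep from their exact Bernoulli
conditionals (data augmentation), which makes ϕ (Beta) and both
precisions (Gamma) conjugate as well.  The augmentation is not merely a
convenience: when no trial is attributed to recall, τ₁'s conditional
collapses to its extremely diffuse prior, over which a random-walk update
mixes badly (this showed up as unstable R-hat in pilot runs of a
marginalized-likelihood sampler), whereas the conjugate draw is i.i.d.
there.  The recorded posterior is identical either way.  Reported
per-trial recall probabilities are marginal mixture responsibilities
averaged over recorded draws.  Convergence is gated at split-chain R-hat
< 1.05 on every parameter (precisions on the log scale); the recovery
pipeline retries a failed fit once with doubled burn-in, then excludes and
counts it.

`FitConfig.desk()` is the schedule used by the recovery grid and the
reproduction script: 2 × 5000 recorded draws (thin 2) after 1000
adaptation + 1000 burn-in iterations.  It keeps the pooled posterior
sample size of the reference schedule — the Savage–Dickey boundary
density estimate depends on it (below) — while cutting sampling
iterations roughly threefold; the posteriors here are unimodal and
low-dimensional, and the shorter schedule moves posterior medians by far
less than their across-replication spread.

## Savage–Dickey Bayes factor

M0 is nested in M1 at ϕ = 0, so BF₁₀ = p(ϕ=0 | M1) / p(ϕ=0 | data, M1);
the numerator is exactly 1 under the Uniform(0,1) prior.  The denominator
must be estimated from posterior samples *at the support boundary*, where
most of the posterior mass may be far away — a tail-extrapolation
problem.  The default estimator is a maximum-likelihood log-spline
density: log f is a natural cubic spline (linear beyond the extreme
knots, i.e. exponential tails) with knots at order statistics — the 1st
and 16th from each end plus evenly spaced interior quantiles — fit by
damped Newton on the concave log-likelihood with the normalizing constant
computed by quadrature over [0, 1].  Knot placement was calibrated
against analytic oracles (uniform, Beta(1,12), truncated exponentials
with known boundary densities): central-only knots systematically flatten
vanishing tails, while stacking three or more knots onto the extreme
ranks makes the boundary slope rest on a handful of points and inflates
its variance.  Two alternatives are selectable via
`FitConfig.density_method`: a reflection KDE (boundary-corrected but
returns ~0 density when no samples are near 0) and a method-of-moments
Beta fit evaluated at half the smallest resolvable quantile (a parametric
boundary convention, useful when samples pile at 0).  The estimator
choice is part of the reported number: when the true boundary density is
0 (e.g. a ϕ posterior ≈ Beta(13,1)), every estimator returns *some*
finite extrapolation and different conventions differ by a few percent in
log BF.  Log BF also grows slowly with the pooled sample size in that
regime (the smallest order statistic moves toward 0), which is why the
desk schedule preserves the pooled 10,000 draws.

## Posterior-predictive RMSE

For every recorded posterior draw, one replicate response is simulated
per trial; the RMSE is computed between observed responses and per-trial
medians over replicates.  For M1, trained-trial replicates condition on
the trial's posterior recall state — the component is chosen with
probability P(z_t = 1 | parameters, y_t), not the marginal ϕ — so an
exactly recalled trial's predictive median sits on its learned criterion.
Replicate simulation is seeded and reproducible.

## Synthetic data generator

The generator emulates the test phase of a multiple-cue judgment
experiment on a 0–100 criterion scale: the full 2^D stimulus space
(default D = 5, 32 stimuli), criteria from a linear-additive rule
c = w₀ + Σ cueᵢ·wᵢ with D+1 weights drawn i.i.d. from a normal(20, 10)
truncated to [0, 100] and rescaled to sum to exactly 100 (the marginals
are therefore only approximately that truncated normal; the sum
constraint and the marginal distribution cannot both hold exactly, and
rescaling is the simplest reconciliation).  Twelve stimuli are drawn as
trained exemplars, never including the two highest- and two lowest-
criterion stimuli (ranked before the swap); one uniformly chosen pair of
*exemplars* then exchanges criterion values, so the trained set is not
perfectly reproducible by the additive rule.  Criteria stay continuous
(no integer rounding).  Each stimulus is judged once: untrained probes
get the exemplar-model prediction at the generating s; each trained probe
is independently a verbatim recall of its learned (post-swap) criterion
with probability P_r, and a model prediction otherwise.  The main regime
adds no response noise, so estimation error is attributable entirely to
the estimator.  With noise_sd > 0, responses are drawn from a normal
truncated to [0, 100] (the response scale is read as a hard bound, not a
clipping rule).  An "empirical" regime draws s and P_r from beta
distributions (method-of-moments defaults: mean .50 / SD .21 for s, mean
.62 / SD .28 for P_r, matched to the participant-level spread of
published experiments on this paradigm) and a per-dataset noise SD from
normal(17, 6) truncated at 0.

What the generator does *not* emulate: training-phase learning curves,
trial repetition or block structure, cue-criterion functions other than
linear-additive, continuous cues, response rounding, and error-prone
recall (recall is verbatim by construction, matching the mixture model's
own assumption).  Passing recovery tests therefore show estimator
behaviour under the model's own idealized conditions, not robustness to
real-data misspecification.

## Recovery study

Grid: true s ∈ {.001, .1, .3, .8} × P_r ∈ {.1, .5, 1}, default 30
replications per cell (200 reproduce the full-scale study; both are
one-flag choices).  Every replication samples a fresh design, generates a
fresh dataset, runs all three fits, the Bayes factor and both RMSEs.
Each (cell, replication) derives an independent RNG stream from the
master seed, so results are bit-exact regardless of execution order.
Expected pattern: ŝ_split and ŝ_int recover the generating s essentially
exactly on noise-free data; ŝ_orig is biased toward 0, increasingly so
with P_r and with s; log BF₁₀ rises with P_r for s ≥ .1 and is mildly
negative at s = .001 (there is almost nothing for the recall component to
explain, so the simpler model wins); M1's predictive RMSE is ~0 on
noise-free data while M0's grows with s and P_r.

## Numerical choices and degenerate inputs

Zero-noise data make several posteriors nearly degenerate on purpose
(precisions grow until the Gamma prior's rate term caps them; s
posteriors have SDs of ~1e−3).  The adaptive proposal handles this by
co-adapting with the growing precision; the conjugate precision draws are
exact at any magnitude; τ₁ draws are floored at 1e−290 so log-scale
diagnostics stay finite under prior underflow.  ϕ's posterior with k
attributed recalls among 12 trained trials is Beta(1+k, 13−k); its median
shrinks toward 1/2, so ϕ̂ under-covers P_r near the boundaries (≈ .95
at P_r = 1, ≈ .13–.18 at P_r = .1) — a prior effect inherent to 12
trained trials, not a sampler artifact (the sampled medians match the
analytic Beta medians to three decimals).  A mixture fit on data without
trained trials requires an explicit exemplar memory and reports a
prior-dominated ϕ with a warning.

## Known limitations

* At s = .001 on noise-free data, recalled responses and model
  predictions differ by ~1e−3 criterion units, so the recall and judgment
  components are empirically indistinguishable; the posterior has two
  well-separated basins (all-recall vs. all-judgment attribution) and
  chains settle in one of them, making ϕ̂ and log BF₁₀
  initialization-dependent in exactly this corner.  No graded quantity
  uses that cell's mixture attribution.
* The ŝ_orig bias magnitudes at high P_r are sensitive to the relative
  weight of recalled vs. judged trials in the likelihood (12:20 in this
  design); designs with other trained fractions shift the bias curve.
* Bayes factors at the support boundary are estimator-convention
  dependent (see above); compare log BF values only within one estimator
  setting.
* Fits are per dataset/participant; no hierarchical pooling.
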