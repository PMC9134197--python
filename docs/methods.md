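# Methods

## The processing tree

The package models two responses per trial — a genuine/posed authenticity
judgment and a valence rating — as the output of a latent multinomial
processing tree. On an emotion trial the perceiver detects the expresser's
feeling state with probability *j*; failing that, they may still report
detection through the response bias *rb* that also governs neutral trials.
Detected trials produce a same-valence experience through sharing (*s*) or,
independently, elicitation (*e*); undetected trials only through
elicitation. Writing D = j + (1−j)·rb for the total detection probability,
the four observable cells are

    θ00 = (1−j)(1−rb)(1−e)        θ10 = D·(1−s)(1−e)
    θ01 = (1−j)(1−rb)·e           θ11 = D·(1 − (1−s)(1−e))

and neutral trials are Bernoulli(rb). `tree.category_probabilities`
implements the expanded six-term form of θ11 exactly as the tree reads;
`tree.collapsed_identities` carries the algebraic collapse above as an
internal cross-check, and a forward branch-sampling simulator serves as the
Monte-Carlo oracle of both.

The likelihood unit is the individual trial (categorical likelihood without
the multinomial coefficient). This choice also fixes the pointwise unit of
WAIC; a participant-level pointwise aggregation can be built from the same
stored matrix but is not the default.

The order of the tree — authenticity judgment before experience — mirrors
the task flow (judgment question first). The package encodes only this
topology; alternative orders (e.g., mimicry-first accounts) are out of
scope.

## Encoding raw responses

A valence rating counts as a same-valence experience when it is strictly
beyond ±1 in the expression's direction (happiness: > +1; anger: < −1).
Because "beyond 1" is ambiguous between strict and weak inequality in
ordinary language, both rules are implemented (`EncodingRule("strict")`,
the default, and `"inclusive"`); valence 0 never qualifies under either.
The rules are nested: every strict same-state trial is inclusive
same-state, which is property-tested.

## Model variants and priors

| variant | free structure |
|---|---|
| M1 | one (j, rb, s, e) for both emotions |
| M2 | j per emotion; rb, s, e shared |
| M3 | j, s, e per emotion; one shared rb (7 parameters) |
| M4 | M3 per participant, independent logit-normal effects |
| M5 | M4 with the 7 effects jointly MVN, correlation ~ LKJ(2) |

M1–M3 place Beta(2, 2) priors on each probability (Beta(1, 1) available as
the sensitivity alternative). The hierarchical variants put Normal(0, 2)
priors on the logit-scale group means α, half-normal(1) priors on the
random-effect scales τ (a scale parameter cannot be negative, so the
half-normal is the positive-support reading of a Normal(0, 1) scale prior),
and subject effects u_n with covariance diag(τ)·Ω·diag(τ).

Two deliberate design choices:

* **Where the correlation lives (M5).** A multivariate prior on the group
  means alone cannot express correlation *across participants* — a single
  draw of α carries no between-subject information. Since the scientific
  target is the correlation among participant-level parameters, the LKJ(2)
  prior is placed on the correlation of the subject effects u_n. The
  group-mean placement is still available (`ModelSpec(mvn_on_alpha=True)`)
  for structural comparisons.
* **One response bias.** Neutral trials measure a single rb; two distinct
  per-emotion rbs are not separable by the design. The default is one rb
  shared across emotions and the neutral condition (7 group parameters);
  an 8-parameter M3 with per-emotion rb exists as an option, in which case
  neutral trials use the average of the two (a modeling convention, not an
  identified quantity).

## Sampling

No general-purpose MCMC engine is assumed: the sampler is an adaptive
random-walk Metropolis-within-Gibbs written for this model family.

* Pooled variants sample the logit-transformed probabilities
  componentwise, plus one joint proposal whose covariance is learned from
  the warmup history (the (s, e) pair is strongly correlated a
  posteriori, which defeats purely componentwise moves).
* Hierarchical variants update, per sweep: each subject-effect column for
  all participants at once (they are conditionally independent given the
  hyperparameters); an independence proposal from each column's
  conditional prior, which re-draws weakly informed components nearly
  freely; a joint per-subject proposal shaped by the current effect
  covariance; the group means, with a likelihood-invariant "shift" move
  (α_k + δ, u·,k − δ) that decouples the group mean from its effects; the
  log effect scales, with an interweaving rescale move (τ_k·e^δ,
  u·,k·e^δ, log-Jacobian n·δ) that resolves the funnel between a scale
  and its effects; and (M5) the correlation parameters.
* The LKJ prior is parametrized by the canonical partial correlations of
  the C-vine construction: with column-specific shifted-Beta priors
  (shape η + (K−2−j)/2 for column j) the implied matrix distribution is
  exactly LKJ(η), so no matrix Jacobian is needed. The construction is
  verified against the known closed-form marginal of an off-diagonal
  element ((r+1)/2 ~ Beta(η−1+K/2, ·)) by a KS test.
* All proposal scales adapt during warmup toward 0.44 acceptance
  (componentwise) or 0.25 (joint blocks), in multiplicative steps every
  50 iterations; adaptation stops at the end of warmup.

Default run lengths are 5000 warmup + 5000 retained draws in each of four
chains, treating "iterations" as post-warmup draws per chain. The test
suite and the acceptance script use shorter, explicitly configured runs
(400–1000 + 400–1000 per chain), which the recovery experiments below show
are sufficient for their purposes. Convergence is monitored with
rank-normalized split R-hat (threshold 1.01); exceeding the threshold
produces a warning naming the worst parameters, never a hard failure.
At reduced draw counts the correlation entries attached to weakly
identified effects (notably anger sharing, see *Identifiability*) can
retain R-hat ≈ 1.1–1.2; their posteriors are prior-dominated and the
warning makes the situation visible.

Point estimates in summaries are posterior density modes (Gaussian-kernel
density, Silverman bandwidth, 512-point grid on the unit interval), with
central 95% intervals from empirical quantiles. The mode can fall outside
the central interval for extremely skewed posteriors; this is warned
about, not rejected.

## WAIC and model comparison

For the draws × trials pointwise log-likelihood matrix, lppd is computed
with a stable log-sum-exp, the effective parameter count is the pointwise
posterior variance (sample variance, n−1 denominator; a single draw gives
0 by convention), and WAIC = −2·(lppd − p_waic) (deviance scale, lower is
better; elpd-scale quantities are exposed too). Pairwise model contrasts
are elpd differences on shared pointwise units with SE =
√(n·var(pointwise diffs)). Posterior predictive checks report, per
participant × condition × category, the observed proportion, the
posterior-mean cell probability, and a central 95% interval from
multinomial replicate datasets; a bar-and-dot plot mirrors the standard
per-participant display.

## Synthetic studies

The generator emulates the target design: 88 participants, 64 anger + 64
happiness + 20 neutral trials each (148 total), per-participant parameters
inverse-logit(α + u_n) with u_n from the correlated hierarchical
population. Defaults: α at the logits of (j_An 0.070, e_An 0.840, s_An
0.006, j_Ha 0.382, e_Ha 0.865, s_Ha 0.965, rb 0.164) — representative
group-level estimates for this paradigm, chosen so default simulations
resemble realistic data (a convenience, not a claim); τ = 0.5 on the logit
scale (moderate, clearly detectable individual differences); Ω = I.

Raw ratings are generated as the exact inverse of the encoding rule
(judgment from the detection digit, valence uniform over the qualifying or
non-qualifying region), so encode(generate_raw(t)) round-trips to t.

Questionnaire items follow a single-factor-per-scale model: latent trait =
loadings · standardized effects + completion noise; item = location +
a·trait + noise with a and the noise SD set from the target inter-item
correlation and mean-score SD, then rounded and clamped to the response
range. The latent location is calibrated by the censored-normal mean
formula so that clamping does not bias scales whose mean sits near a range
end (floor effects in the social-anxiety scales). Default scale
configurations: ECS 15 items on 1–5, IRI subscales 7 items each on 1–5,
SPS/SIAS 20 items on 0–4, with means/SDs and reliabilities (α between 0.66
and 0.93) typical of this population; inter-item correlations are backed
out of the target α by the Spearman–Brown relation. With zero loadings
(default) traits are independent of the tree parameters.

What the generator does *not* emulate: trial exclusions or missing
responses (complete data assumed), stimulus-level crossed random effects
(clips are exchangeable within condition), response styles or
acquiescence in the questionnaires, and any dependence of the valence
rating magnitude on the latent states beyond the qualifying region.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated population model, not robustness to those
real-data complications.

## Identifiability and numerical notes

* Anger sharing (s) at a truth near 0 with elicitation near 0.85 is close
  to the design's information limit: sharing only moves the detected-branch
  "11" rate by s·(1−e) ≈ 0.16·s, and only ≈ 22% of anger trials reach the
  detected branch, giving a delta-method SE of ≈ 0.07 for the pooled fit at
  full study size. Its posterior mean is also shrunk upward by the
  Beta(2, 2) prior (≈ +0.05 at truth 0.006); the posterior mode is the
  less biased point estimate and is what the recovery checks use.
* Interval-calibration experiments draw the generating truths from the
  parameters' own prior, the design under which 95% credible intervals
  cover the truth at the nominal rate by construction; fixed extreme
  truths (like s = 0.006) sit in the prior tail and are not covered at the
  nominal rate by any correct Bayesian procedure.
* Correlation-recovery experiments inject the correlation between the two
  elicitation effects, which are strongly identified per participant;
  injecting on effects the design cannot measure per subject (e.g., anger
  judgment, which is mostly response bias) leaves the posterior at the
  prior regardless of sampler quality.
* Probability cells are floored at 1e−300 inside the samplers (parameters
  are interior under the logit link, so this never binds in practice);
  probability normalization is asserted to 1e−12 absolute; endpoint
  parameter values (exactly 0/1) are accepted by the tree functions for
  analytic tests but excluded from sampling.
* The Bayes factor for a Pearson correlation uses the exact sampling
  density of r (Gauss hypergeometric form) marginalized over a stretched
  Beta(1/κ, 1/κ) prior on ρ (κ = 1, the conventional default, is uniform),
  by trapezoidal quadrature on a 2001-point grid; credible intervals come
  from the gridded posterior CDF. The power analysis inverts the exact
  power function of the two-sided t-test on r by bisection over n; a
  Fisher-z closed form is provided and labeled approximate (it typically
  lands within one or two participants of the exact answer).

## Problem sizes in tests

Recovery tests run at the full design size (88 participants × 148 trials)
with 4 chains of 400–1000 warmup plus as many retained draws — enough for
stable group-level summaries as verified by the emcee cross-check and the
R-hat diagnostics — and 10–20 replicate simulations for the model-recovery
and calibration experiments. Forward-simulator checks use 10⁵ draws per
parameter set; tree-algebra checks use 10⁴ random parameter sets.
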