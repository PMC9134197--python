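# mptshare

Hierarchical Bayesian multinomial-processing-tree (MPT) modeling of how
people come to share an emotion they see on someone else's face.

## The scientific problem

When a perceiver watches a dynamic facial expression of anger or happiness,
they may (a) judge whether the expresser's feeling state is genuine, and
(b) end up reporting a same-valence feeling themselves. The same behavioral
outcome — "I felt what they felt" — can arise through two distinct latent
routes: **sharing** (the feeling follows from detecting the expresser's
genuine state) or mere **elicitation** (the expression evokes the feeling
whether or not it was judged genuine). A multinomial processing tree
disentangles them from two simple responses per trial: a genuine/posed
judgment and a valence rating on −3..+3.

The tree has four branch probabilities per emotion:

| symbol | meaning |
|---|---|
| *j*  | perceiving a feeling state from an emotional expression |
| *rb* | perceiving a feeling state from a neutral expression (response bias) |
| *s*  | sharing the feeling state, given detection |
| *e*  | elicitation of a same-valence feeling, regardless of detection |

Each emotion trial falls into one of four categories "00", "01", "10",
"11" (first digit: detection; second: same-valence experience), with cell
probabilities such as

```
θ00 = (1−j)(1−rb)(1−e)
θ01 = (1−j)(1−rb)e
θ10 = [j + (1−j)rb](1−s)(1−e)
θ11 = [j + (1−j)rb][1 − (1−s)(1−e)]
```

and neutral trials are Bernoulli with θ1 = rb. The package fits this tree
in five variants of increasing structure — M1 (one parameter set for both
emotions), M2 (emotion-specific *j*), M3 (emotion-specific *j*, *s*, *e*
plus one shared *rb*), M4 (M3 with per-participant logit-normal random
effects), M5 (M4 with the seven effects jointly multivariate normal under
an LKJ(2) correlation prior) — compares them by WAIC, checks posterior
predictions per participant, and correlates subject-level effects with
questionnaire traits (ECS, IRI subscales, SPS, SIAS) via Bayes-factor
Pearson correlations.

A synthetic-study generator reproduces the target design (88 participants
× 64 anger + 64 happiness + 20 neutral video-clip trials, plus Likert
questionnaires with controlled reliability), so the entire pipeline is
testable by parameter recovery without any private data.

## Worked example

```python
import numpy as np
import mptshare as m
from mptshare.simulate import PopulationConfig, generate_study
from mptshare.selection import waic, compare

# simulate a complete study at the target design
study = generate_study(PopulationConfig(n_participants=88, seed=1))
trials = m.encode_trials(study.raw_ratings)      # raw ratings -> categories
counts = m.counts_from_trials(trials)

# fit the pooled seven-parameter variant and summarize
sampler = m.SamplerConfig(warmup=1000, draws=1000, chains=4, seed=2)
post3 = m.fit(m.build_model(m.ModelSpec("M3")), counts, sampler)
print(m.summarize(post3).round(3))
```

```
               MAP   2.5%  97.5%
parameter
j_anger      0.059  0.036  0.082
e_anger      0.812  0.802  0.823
s_anger      0.072  0.014  0.163
j_happiness  0.372  0.351  0.391
e_happiness  0.855  0.841  0.868
s_happiness  0.947  0.921  0.967
rb           0.168  0.154  0.189
```

The rows are the seven group-level probabilities (MAP = posterior density
mode, with central 95% intervals). Here the generating population was the
package default — location at `j_anger=0.070, e_anger=0.840, s_anger=0.006,
j_happiness=0.382, e_happiness=0.865, s_happiness=0.965, rb=0.164` with
between-participant spread 0.5 on the logit scale — and the pooled fit
recovers the pattern that matters scientifically: happiness is judged
genuine far more often than anger (0.372 vs 0.059), sharing is near
ceiling for happiness but near floor for anger, and elicitation is high
for both.

Model comparison and the correlated hierarchical variant:

```python
post1 = m.fit(m.build_model(m.ModelSpec("M1")), counts, sampler)
print(compare([waic(post1, "M1"), waic(post3, "M3")]).table)
```

```
model     waic     se  p_waic  rank  elpd_diff_vs_best  diff_se_vs_best
   M3 23389.33 157.21    6.34     1               0.00             0.00
   M1 24691.42 152.72    4.02     2            -651.05            33.68
```

Lower WAIC is better: the emotion-specific tree out-predicts the fully
pooled one by 651 elpd units (SE 34) on this heterogeneous synthetic
cohort, the qualitative ordering the model family is built to detect.

```python
post5 = m.fit(m.build_model(m.ModelSpec("M5")), counts, sampler)
print(m.parameter_correlations(post5))   # 21 pairwise effect correlations
effects = m.extract_subject_effects(post5)
scores = m.score_scales(study.questionnaires)
print(m.trait_parameter_table(effects, scores))  # 7 x 7 Bayes-factor grid
```

Auxiliary design numbers the package computes: the sample size needed to
detect a correlation of 0.3 with 80% power in a two-tailed test at α = .05
is `m.required_n_correlation(0.3) == 84`, from the exact sampling
distribution of the correlation coefficient.

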