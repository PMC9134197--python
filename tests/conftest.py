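import numpy as np
import pytest

import mptshare as m
from mptshare.selection import waic
from mptshare.simulate import PopulationConfig, generate_dataset, generate_population


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def homogeneous_study_counts():
    """An 88-participant study generated with zero between-subject
    heterogeneity (every participant shares the default group parameters),
    i.e. data whose true generating process is the pooled seven-parameter
    model."""
    cfg = PopulationConfig(tau=np.zeros(7), n_participants=88, seed=7)
    params, _ = generate_population(cfg)
    trials = generate_dataset(params, cfg.trials, seed=7)
    return m.counts_from_trials(trials)


@pytest.fixture(scope="session")
def model_recovery_fits():
    """Twenty replicate simulations from the seven-parameter (distinct
    anger/happiness) pooled process, each fitted with both the fully pooled
    one-parameter-set model and the seven-parameter model at reduced draws.

    To keep the resident memory small, each replicate retains only the two
    WAIC results (with their pointwise elpd vectors) and the M3 interval
    summary; the first replicate additionally keeps its fitted M3 posterior
    (pointwise matrix dropped) for posterior-predictive checks.
    """
    sampler = m.SamplerConfig(warmup=400, draws=400, chains=4, seed=13)
    reps = []
    keep_post = None
    for rep in range(20):
        cfg = PopulationConfig(tau=np.zeros(7), n_participants=88, seed=1000 + rep)
        params, _ = generate_population(cfg)
        counts = m.counts_from_trials(generate_dataset(params, cfg.trials, 1000 + rep))
        truth = {k: float(params.iloc[0][k]) for k in m.EFFECT_NAMES}
        p1 = m.fit(m.build_model(m.ModelSpec("M1")), counts, sampler)
        p3 = m.fit(m.build_model(m.ModelSpec("M3")), counts, sampler)
        entry = {
            "truth": truth,
            "waic_m1": waic(p1, "M1"),
            "waic_m3": waic(p3, "M3"),
            "summary_m3": m.summarize(p3),
        }
        if rep == 0:
            p3.pointwise = None  # PPC needs draws + counts, not the matrix
            keep_post = p3
        reps.append(entry)
    return {"reps": reps, "m3_post": keep_post}


@pytest.fixture(scope="session")
def prior_calibrated_fits():
    """Twenty replicates whose generating parameters are themselves drawn
    from the Beta(2, 2) prior, the self-consistent design for checking
    credible-interval calibration (under it, 95% intervals cover the truth
    95% of the time by construction).  Only the interval summaries are
    retained."""
    from scipy.special import logit

    sampler = m.SamplerConfig(
        warmup=400, draws=400, chains=4, seed=29, store_pointwise=False
    )
    master = np.random.default_rng(77)
    reps = []
    for rep in range(20):
        truth_p = master.beta(2.0, 2.0, size=7)
        cfg = PopulationConfig(
            alpha=logit(truth_p), tau=np.zeros(7), n_participants=88,
            seed=2000 + rep,
        )
        params, _ = generate_population(cfg)
        counts = m.counts_from_trials(
            generate_dataset(params, cfg.trials, 2000 + rep)
        )
        post = m.fit(m.build_model(m.ModelSpec("M3")), counts, sampler)
        reps.append(
            {
                "truth": dict(zip(m.EFFECT_NAMES, truth_p)),
                "summary": m.summarize(post),
            }
        )
    return reps
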