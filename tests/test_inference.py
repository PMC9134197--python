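"""Model construction, MCMC, diagnostics and posterior summaries."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import mptshare as m
from mptshare.inference import (
    CountsData,
    _pooled_cells,
    _vine_shapes,
    corr_from_partials,
)
from mptshare.tree import EMOTION_CATEGORIES


def test_build_model_parameter_counts():
    assert len(m.build_model(m.ModelSpec("M1")).param_names) == 4
    assert len(m.build_model(m.ModelSpec("M2")).param_names) == 5
    m3 = m.build_model(m.ModelSpec("M3"))
    assert m3.param_names == m.EFFECT_NAMES  # 7: j/e/s per emotion + rb
    assert len(m.build_model(m.ModelSpec("M3", shared_rb=False)).param_names) == 8
    m5 = m.build_model(m.ModelSpec("M5"))
    assert m5.hierarchical
    # dimensional bookkeeping: 7 means + 7 scales + 21 correlations
    # + 7 effects per subject (checked against the stored draws below)
    with pytest.raises(ValueError):
        m.ModelSpec("M7")
    with pytest.raises(ValueError):
        m.ModelSpec("M4", shared_rb=False)


def test_pooled_cells_match_tree():
    model = m.build_model(m.ModelSpec("M3"))
    p = np.array([0.1, 0.8, 0.05, 0.4, 0.85, 0.9, 0.2])
    cells = _pooled_cells(model, p)
    anger = m.category_probabilities(
        m.MPTParameters(j=0.1, rb=0.2, s=0.05, e=0.8), "anger"
    ).as_array()
    np.testing.assert_allclose(cells[:4], anger, atol=1e-12)
    assert cells[8] == pytest.approx(0.2)
    np.testing.assert_allclose(cells.sum(), 2 + 1, atol=1e-12)


def test_prior_recovery_with_empty_data():
    """With no data every M1 parameter's posterior is its Beta(2, 2) prior."""
    post = m.fit(
        m.build_model(m.ModelSpec("M1")),
        [],
        m.SamplerConfig(warmup=500, draws=5000, chains=4, seed=42),
    )
    for name, draws in post.group.items():
        assert abs(draws.mean() - 0.5) < 0.02, name
        assert abs(draws.var() - 0.05) < 0.01, name


def test_all_zero_category_concentrates_e_and_detection_near_zero():
    counts = [
        m.ResponseCounts("p1", "anger", {"00": 600}),
        m.ResponseCounts("p1", "happiness", {"00": 600}),
        m.ResponseCounts("p1", "neutral", {"0": 100}),
    ]
    post = m.fit(
        m.build_model(m.ModelSpec("M1")),
        counts,
        m.SamplerConfig(warmup=800, draws=1500, chains=4, seed=7),
    )
    e = np.concatenate([post.group["e"].reshape(-1)])
    j, rb = post.stacked("j"), post.stacked("rb")
    detect = j + (1 - j) * rb
    assert np.quantile(e, 0.95) < 0.05
    assert np.quantile(detect, 0.95) < 0.05


def test_m1_posterior_matches_independent_ensemble_sampler(
    homogeneous_study_counts,
):
    """Cross-check the in-house sampler against an affine-invariant
    ensemble sampler (emcee) on the identical log posterior."""
    emcee = pytest.importorskip("emcee")
    model = m.build_model(m.ModelSpec("M1"))
    data = CountsData.from_counts(homogeneous_study_counts)
    total = data.cell_matrix().sum(axis=0).astype(float)

    def log_post(x):
        p = expit(x)
        lp = float(np.sum(2 * np.log(p) + 2 * np.log1p(-p)))
        cells = _pooled_cells(model, p)
        return lp + float(total @ np.log(np.clip(cells, 1e-300, None)))

    nwalkers, ndim = 16, 4
    rng = np.random.default_rng(0)
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post)
    sampler.random_state = np.random.RandomState(123)
    sampler.run_mcmc(rng.normal(0, 0.3, (nwalkers, ndim)), 4000, progress=False)
    ref = expit(sampler.get_chain(discard=1500, flat=True))

    post = m.fit(
        model, data, m.SamplerConfig(warmup=800, draws=1200, chains=4, seed=3)
    )
    for k, name in enumerate(model.param_names):
        ours = post.stacked(name)
        assert abs(ours.mean() - ref[:, k].mean()) < 0.012, name
        assert abs(ours.std() - ref[:, k].std()) < 0.012, name


def test_m3_group_recovery(homogeneous_study_counts):
    """Study-size seven-parameter fit recovers the generating values."""
    from mptshare.simulate import DEFAULT_GROUP_PROBS

    post = m.fit(
        m.build_model(m.ModelSpec("M3")),
        homogeneous_study_counts,
        m.SamplerConfig(warmup=1000, draws=1000, chains=4, seed=2),
    )
    summ = m.summarize(post)
    for name in m.EFFECT_NAMES:
        assert abs(summ.loc[name, "MAP"] - DEFAULT_GROUP_PROBS[name]) < 0.05, name


def test_pointwise_loglik_consistent_with_tree_oracle(homogeneous_study_counts):
    """The stored pointwise matrix equals the categorical log-likelihood
    recomputed per trial from the same draws' parameters."""
    data = CountsData.from_counts(homogeneous_study_counts)
    post = m.fit(
        m.build_model(m.ModelSpec("M1")),
        data,
        m.SamplerConfig(warmup=300, draws=100, chains=2, seed=5),
    )
    part_idx, cell_idx = data.trial_expansion()
    cond_of_cell = ["anger"] * 4 + ["happiness"] * 4 + ["neutral"] * 2
    cat_of_cell = list(EMOTION_CATEGORIES) * 2 + ["1", "0"]
    for s in [0, 57, 199]:
        pars = m.MPTParameters(
            j=post.stacked("j")[s], rb=post.stacked("rb")[s],
            s=post.stacked("s")[s], e=post.stacked("e")[s],
        )
        for trial in [0, 1000, 7000, len(cell_idx) - 1]:
            cell = cell_idx[trial]
            theta = m.category_probabilities(pars, cond_of_cell[cell])
            counts1 = m.ResponseCounts(
                "x", cond_of_cell[cell], {cat_of_cell[cell]: 1}
            )
            expected = m.log_likelihood(counts1, theta)
            assert post.pointwise[s, trial] == pytest.approx(expected, rel=1e-5)


def test_rhat_behavior(rng):
    iid = rng.standard_normal((4, 2000))
    assert m.rhat({"x": iid})["x"] < 1.01
    shifted = iid + 5 * np.arange(4)[:, None]
    assert m.rhat({"x": shifted})["x"] > 1.1
    assert np.isnan(m.rhat({"x": np.ones((4, 100))})["x"])
    with pytest.raises(ValueError, match="chains"):
        m.rhat({"x": np.ones((1, 100))})


def test_summarize_beta_mode_and_quantiles(rng):
    draws = rng.beta(2, 8, size=(4, 5000))
    post = m.PosteriorDraws(
        variant="M1",
        spec=m.ModelSpec("M1"),
        param_names=("p",),
        group={"p": draws},
        participants=[],
        data=None,
    )
    summ = m.summarize(post)
    assert abs(summ.loc["p", "MAP"] - 1 / 8) < 0.03
    assert summ.loc["p", "2.5%"] == pytest.approx(
        np.quantile(draws, 0.025), abs=1e-12
    )
    assert summ.loc["p", "97.5%"] == pytest.approx(
        np.quantile(draws, 0.975), abs=1e-12
    )
    small = m.PosteriorDraws(
        variant="M1", spec=m.ModelSpec("M1"), param_names=("p",),
        group={"p": draws[:, :20]}, participants=[], data=None,
    )
    with pytest.raises(ValueError, match="100 draws"):
        m.summarize(small)


def test_symmetric_posterior_map_near_median(rng):
    draws = rng.normal(0.5, 0.05, size=(4, 4000)).clip(0.01, 0.99)
    post = m.PosteriorDraws(
        variant="M1", spec=m.ModelSpec("M1"), param_names=("p",),
        group={"p": draws}, participants=[], data=None,
    )
    summ = m.summarize(post)
    assert abs(summ.loc["p", "MAP"] - np.median(draws)) < 0.5 * draws.std()


@pytest.fixture(scope="module")
def small_hierarchical_fit():
    from mptshare.simulate import PopulationConfig, generate_dataset, generate_population

    om = np.eye(7)
    om[1, 4] = om[4, 1] = 0.5  # couple the two well-identified elicitations
    cfg = PopulationConfig(
        tau=np.full(7, 0.5), omega=om, n_participants=30, seed=17
    )
    params, effects = generate_population(cfg)
    counts = m.counts_from_trials(generate_dataset(params, cfg.trials, 17))
    post = m.fit(
        m.build_model(m.ModelSpec("M5")),
        counts,
        m.SamplerConfig(warmup=500, draws=500, chains=2, seed=4),
    )
    return post, effects


def test_extract_subject_effects(small_hierarchical_fit):
    post, true_effects = small_hierarchical_fit
    eff = m.extract_subject_effects(post)
    assert eff.shape == (30, 7)
    assert list(eff.index) == post.participants
    # shrunken but sign-consistent with truth for well-identified effects
    r = np.corrcoef(eff["e_happiness"], true_effects["e_happiness"])[0, 1]
    assert r > 0.5
    probs = m.extract_subject_effects(post, scale="probability")
    assert ((probs > 0) & (probs < 1)).all().all()


def test_extract_subject_effects_requires_hierarchical(homogeneous_study_counts):
    post = m.fit(
        m.build_model(m.ModelSpec("M1")),
        homogeneous_study_counts,
        m.SamplerConfig(warmup=200, draws=200, chains=2, seed=1),
    )
    with pytest.raises(ValueError, match="hierarchical"):
        m.extract_subject_effects(post)
    with pytest.raises(ValueError, match="M5"):
        m.parameter_correlations(post)


def test_parameter_correlations_layout_and_sign(small_hierarchical_fit):
    post, _ = small_hierarchical_fit
    table = m.parameter_correlations(post)
    assert len(table) == 21  # unordered pairs of 7 effects
    pairs = set(zip(table.parameter_a, table.parameter_b))
    assert len(pairs) == 21
    row = table[
        (table.parameter_a == "e_anger") & (table.parameter_b == "e_happiness")
    ].iloc[0]
    assert row["median"] > 0  # injected positive coupling


def test_m5_dimensional_bookkeeping(small_hierarchical_fit):
    post, _ = small_hierarchical_fit
    assert post.alpha.shape[-1] == 7
    assert post.tau.shape[-1] == 7
    assert post.u.shape[-2:] == (30, 7)
    assert post.omega.shape[-2:] == (7, 7)
    scalars = post.scalar_draws()
    assert sum(k.startswith("omega[") for k in scalars) == 21
    # every stored correlation matrix is a valid correlation matrix
    om = post.omega.reshape(-1, 7, 7)[::97]
    assert np.allclose(np.diagonal(om, axis1=1, axis2=2), 1.0, atol=1e-8)
    assert (np.linalg.eigvalsh(om) > -1e-8).all()


def test_vine_partial_correlations_realize_lkj_marginals(rng):
    """Under the vine construction with the layer-specific Beta shapes, an
    off-diagonal correlation has the known LKJ marginal."""
    k, eta = 7, 2.0
    shapes = _vine_shapes(k, eta)
    samples = []
    for _ in range(3000):
        z = 2 * rng.beta(shapes, shapes) - 1
        om = corr_from_partials(z, k)
        samples.append((om[1, 0], om[6, 5]))
    samples = np.asarray(samples)
    b = eta - 1 + k / 2
    for col in range(2):
        w = (samples[:, col] + 1) / 2
        assert stats.kstest(w, "beta", args=(b, b)).pvalue > 0.001


def test_hierarchical_fit_requires_multiple_participants():
    counts = [m.ResponseCounts("only", "anger", {"00": 10})]
    with pytest.raises(ValueError, match="participants"):
        m.fit(
            m.build_model(m.ModelSpec("M4")),
            counts,
            m.SamplerConfig(warmup=10, draws=10, chains=2, seed=0),
        )


def test_sampler_config_validation():
    with pytest.raises(ValueError, match="chains"):
        m.SamplerConfig(chains=1)
    with pytest.raises(ValueError, match="draws"):
        m.SamplerConfig(draws=0)


def test_beta_prior_sensitivity_runs_and_reports_both(homogeneous_study_counts):
    """The flat-prior alternative fits and yields a comparable WAIC; both
    numbers are reported so prior sensitivity can be assessed on any data."""
    from mptshare.selection import waic

    cfgS = m.SamplerConfig(warmup=300, draws=300, chains=2, seed=9)
    w_beta = waic(
        m.fit(m.build_model(m.ModelSpec("M3")), homogeneous_study_counts, cfgS)
    )
    w_flat = waic(
        m.fit(
            m.build_model(m.ModelSpec("M3", beta_prior=(1.0, 1.0))),
            homogeneous_study_counts,
            cfgS,
        )
    )
    assert np.isfinite(w_beta.waic) and np.isfinite(w_flat.waic)
    assert abs(w_beta.waic - w_flat.waic) < 50
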