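"""WAIC, model comparison, and posterior predictive checks."""

import numpy as np
import pytest

import mptshare as m
from mptshare.inference import CountsData
from mptshare.selection import compare, posterior_predictive_check, waic


def waic_double_loop(ll):
    """Naive reference implementation with explicit loops."""
    s, n = ll.shape
    lppd = 0.0
    p_waic = 0.0
    elpd_i = np.empty(n)
    for i in range(n):
        lppd_i = np.log(np.mean(np.exp(ll[:, i])))
        var_i = np.var(ll[:, i], ddof=1) if s > 1 else 0.0
        lppd += lppd_i
        p_waic += var_i
        elpd_i[i] = lppd_i - var_i
    return lppd, p_waic, -2 * (lppd - p_waic), elpd_i


def test_waic_two_draw_hand_example():
    res = waic(np.array([[np.log(0.5)], [np.log(0.25)]]))
    assert res.lppd == pytest.approx(np.log(0.375), abs=1e-5)
    assert res.p_waic == pytest.approx(0.24023, abs=1e-4)
    assert res.waic == pytest.approx(2.44212, abs=1e-4)


def test_waic_constant_loglik():
    ll = np.tile(np.log([0.2, 0.5, 0.1]), (10, 1))
    res = waic(ll)
    assert res.p_waic == pytest.approx(0.0, abs=1e-12)
    assert res.waic == pytest.approx(-2 * ll[0].sum(), abs=1e-10)


def test_waic_single_draw_convention():
    res = waic(np.log([[0.3, 0.6]]))
    assert res.p_waic == 0.0
    assert res.waic == pytest.approx(-2 * np.log(0.18), abs=1e-10)


def test_waic_matches_double_loop_oracle(rng):
    """Vectorized WAIC equals the naive double-loop to 1e−10 on random
    matrices, and the identity waic = −2(lppd − p_waic) holds."""
    for _ in range(5):
        ll = np.log(rng.random((50, 20)) * 0.9 + 0.05)
        res = waic(ll)
        lppd, p_waic, w, elpd_i = waic_double_loop(ll)
        assert res.lppd == pytest.approx(lppd, abs=1e-10)
        assert res.p_waic == pytest.approx(p_waic, abs=1e-10)
        assert res.waic == pytest.approx(w, abs=1e-10)
        np.testing.assert_allclose(res.pointwise_elpd, elpd_i, atol=1e-10)
        assert res.waic == pytest.approx(-2 * (res.lppd - res.p_waic), abs=1e-10)
        assert res.p_waic >= 0


def test_waic_matches_arviz(rng):
    """Independent cross-check on the elpd scale against arviz."""
    az = pytest.importorskip("arviz")
    ll = np.log(rng.random((4, 100, 30)) * 0.9 + 0.05)
    idata = az.from_dict(log_likelihood={"y": ll})
    with np.errstate(all="ignore"):
        ref = az.waic(idata, scale="deviance")
    res = waic(ll.reshape(-1, 30))
    # arviz computes the pointwise variance with the population (ddof=0)
    # convention; align before comparing
    s = ll.shape[0] * ll.shape[1]
    adjusted = -2 * (res.lppd - res.p_waic * (s - 1) / s)
    assert adjusted == pytest.approx(float(ref.elpd_waic), rel=1e-6)
    assert res.waic == pytest.approx(float(ref.elpd_waic), rel=5e-3)


def test_waic_rejects_nonfinite():
    ll = np.log([[0.5, 0.2], [0.1, 0.0]])
    with pytest.raises(ValueError, match="trial indices"):
        waic(ll)


def test_waic_pointwise_additivity(rng):
    """Duplicating a trial column adds exactly its pointwise elpd."""
    ll = np.log(rng.random((20, 10)) * 0.9 + 0.05)
    base = waic(ll)
    extended = waic(np.concatenate([ll, ll[:, :1]], axis=1))
    assert extended.elpd == pytest.approx(
        base.elpd + base.pointwise_elpd[0], abs=1e-9
    )


def test_compare_identical_and_antisymmetry(rng):
    ll = np.log(rng.random((30, 15)) * 0.9 + 0.05)
    a, b = waic(ll, "A"), waic(ll, "B")
    res = compare([a, b])
    self_diff = res.pairwise[
        (res.pairwise.model_a == "A") & (res.pairwise.model_b == "B")
    ].iloc[0]
    assert self_diff.elpd_diff == 0.0 and self_diff.se == 0.0
    ll2 = np.log(rng.random((30, 15)) * 0.9 + 0.05)
    c = waic(ll2, "C")
    res = compare([a, c])
    d_ac = res.pairwise[
        (res.pairwise.model_a == "A") & (res.pairwise.model_b == "C")
    ].iloc[0]
    d_ca = res.pairwise[
        (res.pairwise.model_a == "C") & (res.pairwise.model_b == "A")
    ].iloc[0]
    assert d_ac.elpd_diff == pytest.approx(-d_ca.elpd_diff, abs=1e-12)
    assert d_ac.se == pytest.approx(d_ca.se, abs=1e-12)


def test_compare_rejects_mismatched_lengths(rng):
    a = waic(np.log(rng.random((5, 10)) + 0.05), "A")
    b = waic(np.log(rng.random((5, 11)) + 0.05), "B")
    with pytest.raises(ValueError, match="mismatched"):
        compare([a, b])


def test_compare_ranks_lower_waic_first(rng):
    good = waic(np.log(np.full((10, 20), 0.8)), "good")
    bad = waic(np.log(np.full((10, 20), 0.3)), "bad")
    res = compare([bad, good])
    assert res.table.iloc[0]["model"] == "good"
    assert res.best().name == "good"


def _point_mass_posterior(theta_params, counts):
    """Posterior that is a point mass at one parameter set."""
    model = m.build_model(m.ModelSpec("M3"))
    data = CountsData.from_counts(counts)
    p = np.array([theta_params[k] for k in m.EFFECT_NAMES])
    group = {
        name: np.full((2, 200), p[i]) for i, name in enumerate(m.EFFECT_NAMES)
    }
    return m.PosteriorDraws(
        variant="M3", spec=model.spec, param_names=m.EFFECT_NAMES,
        group=group, participants=data.participants, data=data,
    )


def test_ppc_point_mass_posterior_equals_analytic_cells():
    theta = {
        "j_anger": 0.1, "e_anger": 0.8, "s_anger": 0.1,
        "j_happiness": 0.4, "e_happiness": 0.85, "s_happiness": 0.9,
        "rb": 0.2,
    }
    counts = [
        m.ResponseCounts("p1", "anger", {"00": 10, "01": 30, "10": 4, "11": 20}),
        m.ResponseCounts("p1", "neutral", {"1": 5, "0": 15}),
    ]
    post = _point_mass_posterior(theta, counts)
    ppc = posterior_predictive_check(post, n_draws=100, seed=1)
    anger = ppc[(ppc.condition == "anger")].set_index("category")
    analytic = m.category_probabilities(
        m.MPTParameters(j=0.1, rb=0.2, s=0.1, e=0.8), "anger"
    )
    for cat in ("00", "01", "10", "11"):
        assert anger.loc[cat, "predicted_mean"] == pytest.approx(
            analytic[cat], abs=1e-9
        )
    neutral = ppc[ppc.condition == "neutral"].set_index("category")
    assert neutral.loc["1", "predicted_mean"] == pytest.approx(0.2, abs=1e-9)


def test_ppc_calibration_on_well_specified_simulation(model_recovery_fits):
    """About 95% of observed cells fall inside the 95% predictive bands
    when the fitted model generated the data."""
    post = model_recovery_fits["m3_post"]
    ppc = posterior_predictive_check(post, n_draws=300, seed=2)
    ok = (ppc.observed >= ppc.predicted_lo) & (ppc.observed <= ppc.predicted_hi)
    assert 0.90 <= ok.mean() <= 1.0


def test_hierarchical_predicts_heterogeneous_subjects_better():
    """With real between-subject spread, the hierarchical fit tracks each
    participant's frequencies more closely than complete pooling."""
    from mptshare.simulate import PopulationConfig, generate_dataset, generate_population

    cfg = PopulationConfig(tau=np.full(7, 0.8), n_participants=24, seed=31)
    params, _ = generate_population(cfg)
    counts = m.counts_from_trials(generate_dataset(params, cfg.trials, 31))
    cfgS = m.SamplerConfig(warmup=400, draws=400, chains=2, seed=8)
    pooled = m.fit(m.build_model(m.ModelSpec("M3")), counts, cfgS)
    hier = m.fit(m.build_model(m.ModelSpec("M4")), counts, cfgS)
    mae = {}
    for name, post in [("pooled", pooled), ("hier", hier)]:
        ppc = posterior_predictive_check(post, n_draws=200, seed=3)
        mae[name] = (ppc.observed - ppc.predicted_mean).abs().mean()
    assert mae["hier"] < mae["pooled"]


def test_ppc_unknown_participant_raises():
    # hierarchical fits must refuse participants they have not seen
    from mptshare.simulate import PopulationConfig, generate_dataset, generate_population

    cfg = PopulationConfig(tau=np.full(7, 0.5), n_participants=3, seed=41)
    params, _ = generate_population(cfg)
    counts = m.counts_from_trials(generate_dataset(params, cfg.trials, 41))
    hier = m.fit(
        m.build_model(m.ModelSpec("M4")),
        counts,
        m.SamplerConfig(warmup=100, draws=100, chains=2, seed=1),
    )
    stranger = [m.ResponseCounts("zz_new", "anger", {"00": 5})]
    with pytest.raises(ValueError, match="absent"):
        posterior_predictive_check(hier, stranger)


def test_plot_ppc_writes_figure(tmp_path, model_recovery_fits):
    from mptshare.selection import plot_ppc

    post = model_recovery_fits["m3_post"]
    ppc = posterior_predictive_check(post, n_draws=50, seed=4)
    out = tmp_path / "ppc.png"
    plot_ppc(ppc, post.participants[:3], path=str(out))
    assert out.exists() and out.stat().st_size > 0
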