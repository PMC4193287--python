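import math

import numpy as np
import pytest
from scipy.stats import norm

import netsig.bias_simulator as bs
from netsig.bias_simulator import (
    CopasSelection,
    PValueSelection,
    ScenarioSpec,
    SizeModel,
    copas_gammas,
    copas_selected,
    draw_network_effects,
    pvalue_selected,
    simulate_biased_network,
    simulate_meta_analysis,
)
from netsig.excess_test import _observed_significant
from netsig.plausible_effects import per_trial_effect


def test_scenario_spec_validation():
    with pytest.raises(ValueError):
        ScenarioSpec(J=0)
    with pytest.raises(ValueError):
        ScenarioSpec(tau2=-0.1)
    with pytest.raises(ValueError):
        ScenarioSpec(rate_range=(0.0, 0.7))
    with pytest.raises(ValueError):
        ScenarioSpec(J=3, theta_j=(0.5, 0.5))  # wrong length
    with pytest.raises(ValueError):
        CopasSelection(rho_min=0.5, rho_max=0.2)


def test_draw_network_effects_degenerate_and_moments(rng):
    assert np.allclose(draw_network_effects(5, math.log(0.75), 0.0, rng=rng),
                       0.75)
    draws = np.log(draw_network_effects(100_000, math.log(0.75), 0.02, rng=rng))
    assert draws.mean() == pytest.approx(math.log(0.75),
                                         abs=3 * math.sqrt(0.02 / 100_000))
    assert draws.var() == pytest.approx(0.02, rel=0.05)


def test_simulate_meta_analysis_shape_and_determinism():
    ma1 = simulate_meta_analysis(3, 0.75, 0.08, seed=42)
    ma2 = simulate_meta_analysis(3, 0.75, 0.08, seed=42)
    assert ma1 == ma2
    assert ma1.n_j == 3 and ma1.variant == "binary"
    assert simulate_meta_analysis(3, 0.75, 0.08, seed=43) != ma1


def test_simulate_meta_analysis_null_homogeneous(rng):
    ma = simulate_meta_analysis(200, 1.0, 0.0, rate_range=(0.5, 0.5),
                                size_model=SizeModel(median=100, log_sd=0.0),
                                rng=rng)
    events = np.array([[t.x_E, t.x_C] for t in ma.trials])
    assert all(t.n_E == t.n_C == 100 for t in ma.trials)
    # both arms Binomial(100, 0.5): mean within 4 SE
    se = math.sqrt(0.25 / 100 / 400)
    assert events.mean() / 100 == pytest.approx(0.5, abs=4 * se)


def test_simulate_meta_analysis_moment_recovery(rng):
    """Generated log odds ratios recover the true mean and between-trial
    variance within Monte-Carlo error."""
    n = 10_000
    ma = simulate_meta_analysis(n, 0.75, 0.08, rate_range=(0.4, 0.6),
                                size_model=SizeModel(median=200, log_sd=0.0,
                                                     max_size=200),
                                rng=rng)
    effects = np.array([per_trial_effect(t) for t in ma.trials])
    y, se = effects[:, 0], effects[:, 1]
    assert y.mean() == pytest.approx(math.log(0.75), abs=3 * y.std() / math.sqrt(n))
    # total variance = tau2 + average sampling variance
    assert y.var() == pytest.approx(0.08 + np.mean(se ** 2), rel=0.10)


def test_pvalue_selector_extremes_and_frequency(rng):
    assert pvalue_selected(0.2, 1.0, rng)
    assert pvalue_selected(0.01, 0.0, rng)
    assert not pvalue_selected(0.2, 0.0, rng)
    kept = sum(pvalue_selected(0.5, 0.3, rng) for _ in range(20_000))
    assert kept / 20_000 == pytest.approx(0.3, abs=4 * math.sqrt(0.3 * 0.7 / 20_000))


def test_pvalue_selector_weight_one_is_seed_matched_noop():
    spec_plain = ScenarioSpec(J=3, n=4, theta_j=(0.8, 1.0, 0.7), tau2=0.05,
                              seed=9)
    spec_sel = ScenarioSpec(J=3, n=4, theta_j=(0.8, 1.0, 0.7), tau2=0.05,
                            seed=9, selection=PValueSelection(weight_nonsig=1.0))
    assert simulate_biased_network(spec_plain) == simulate_biased_network(spec_sel)


def test_copas_marginal_selection_rate_at_rho_zero(rng):
    g0, g1 = copas_gammas()
    se = 0.4
    kept = sum(copas_selected(rng.normal(0, se), se, 0.0, g0, g1, rng)
               for _ in range(20_000))
    expect = norm.cdf(g0 + g1 / se)
    assert kept / 20_000 == pytest.approx(
        expect, abs=4 * math.sqrt(expect * (1 - expect) / 20_000))


def test_copas_gamma_anchors():
    sm = SizeModel()
    g0, g1 = copas_gammas(sm, p_select_median=0.7, p_select_largest=0.9)
    se_med = math.sqrt(2 / (sm.median * 0.5) + 2 / (sm.median * 0.5))
    se_big = math.sqrt(2 / (sm.max_size * 0.5) + 2 / (sm.max_size * 0.5))
    assert norm.cdf(g0 + g1 / se_med) == pytest.approx(0.7, abs=1e-12)
    assert norm.cdf(g0 + g1 / se_big) == pytest.approx(0.9, abs=1e-12)


def test_copas_selection_favours_benefit(rng):
    """At high rho the retained trials show more extreme benefit (smaller
    log odds ratio) than the full candidate stream."""
    g0, g1 = copas_gammas()
    se = 0.4
    effects = rng.normal(0.0, se, 30_000)
    kept = np.array([copas_selected(y, se, 0.8, g0, g1, rng) for y in effects])
    assert kept.mean() > 0.2
    assert effects[kept].mean() < effects.mean() - 0.01


def test_biased_network_shape_and_excess_significance():
    """Size-and-effect selection inflates the observed significant count
    relative to seed-matched unbiased generation."""
    vec = (0.75, 0.8, 0.7, 0.85)
    base = dict(J=4, n=5, theta_j=vec, tau2=0.05)
    O_plain, O_sel = 0, 0
    for r in range(150):
        plain = simulate_biased_network(ScenarioSpec(**base), seed=1000 + r)
        sel = simulate_biased_network(
            ScenarioSpec(**base, selection=CopasSelection(0.5, 0.8)),
            seed=1000 + r)
        assert all(ma.n_j == 5 for ma in sel.meta_analyses)
        O_plain += sum(sum(_observed_significant(ma, 0.05))
                       for ma in plain.meta_analyses)
        O_sel += sum(sum(_observed_significant(ma, 0.05))
                     for ma in sel.meta_analyses)
    assert O_sel > O_plain


def test_generation_cap_raises(monkeypatch):
    monkeypatch.setattr(bs, "GENERATION_CAP", 20)
    spec = ScenarioSpec(J=1, n=5, theta_j=(1.0,), tau2=0.0,
                        size_model=SizeModel(median=10, log_sd=0.0, max_size=10),
                        selection=PValueSelection(weight_nonsig=0.0))
    with pytest.raises(RuntimeError, match="generation cap"):
        simulate_biased_network(spec, seed=3)
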