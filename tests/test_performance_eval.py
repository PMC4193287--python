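import math

import numpy as np
import pytest

from netsig.bias_simulator import CopasSelection, ScenarioSpec, SizeModel
from netsig.performance_eval import (
    adjusted_power,
    arcsine_comparator,
    empirical_type1,
    evaluate_pair,
    likelihood_ratios,
    replicate_pvalues,
    run_grid,
)
from netsig.trial_model import MetaAnalysisData, TwoArmBinaryTrial

SMALL_NULL = ScenarioSpec(J=3, n=3, theta_j=(0.8, 1.0, 0.75), tau2=0.02,
                          size_model=SizeModel(median=40, max_size=200),
                          reps=40, seed=5)


def test_adjusted_power_sort_and_count_oracle(rng):
    null_p = rng.uniform(0, 1, 1000)
    alt_p = rng.beta(0.3, 1.0, 1000)
    t_star = np.quantile(null_p, 0.10)
    expected = np.sum(np.sort(alt_p) <= t_star) / 1000
    assert adjusted_power(null_p, alt_p, 0.10) == pytest.approx(expected)


def test_adjusted_power_self_calibration_and_extremes(rng):
    null_p = rng.uniform(0, 1, 5000)
    assert adjusted_power(null_p, null_p, 0.10) == pytest.approx(0.10, abs=0.01)
    assert adjusted_power(null_p, np.zeros(50), 0.10) == 1.0
    with pytest.raises(ValueError):
        adjusted_power(np.array([]), null_p)


@pytest.mark.parametrize("power,type1,expected", [
    (0.5, 0.10, (5.0, 0.5 / 0.9)),
    (0.9, 0.05, (18.0, 0.1 / 0.95)),
    (0.3, 0.3, (1.0, 1.0)),
])
def test_likelihood_ratio_arithmetic(power, type1, expected):
    lr_pos, lr_neg = likelihood_ratios(type1, power)
    assert lr_pos == pytest.approx(expected[0])
    assert lr_neg == pytest.approx(expected[1])
    # identities hold exactly
    assert lr_pos * type1 == pytest.approx(power, abs=1e-15)
    assert lr_neg * (1 - type1) == pytest.approx(1 - power, abs=1e-15)


def test_likelihood_ratio_degenerate_rates():
    lr_pos, lr_neg = likelihood_ratios(0.0, 0.5)
    assert math.isinf(lr_pos)
    lr_pos, lr_neg = likelihood_ratios(1.0, 0.5)
    assert math.isnan(lr_neg)


def _mirror_ma():
    """Mirror-image trial pairs: identical sizes, event counts swapped, so
    the funnel is exactly symmetric."""
    pairs = [(30, 9, 15), (60, 20, 30), (120, 40, 55), (200, 70, 95)]
    trials = []
    for n, lo, hi in pairs:
        trials.append(TwoArmBinaryTrial(x_E=lo, n_E=n, x_C=hi, n_C=n,
                                        trial_id=f"a{n}"))
        trials.append(TwoArmBinaryTrial(x_E=hi, n_E=n, x_C=lo, n_C=n,
                                        trial_id=f"b{n}"))
    return MetaAnalysisData(comparison=("e", "c"), trials=tuple(trials))


def test_arcsine_comparator_symmetric_funnel_has_zero_slope():
    res = arcsine_comparator(_mirror_ma())
    assert res["applicable"]
    assert res["slope"] == pytest.approx(0.0, abs=1e-12)
    assert res["p_value"] == pytest.approx(1.0, abs=1e-9)


def test_arcsine_comparator_detects_strong_trend():
    # effects manufactured to rise steeply with SE: small trials show a
    # large arcsine difference, big trials almost none
    trials = []
    for n in (50, 100, 200, 400, 800, 1600, 3200, 6400):
        se = math.sqrt(1 / (2 * n))
        target = 5.0 * se
        x_C = n // 2
        # closest integer event count to the target arcsine difference
        best = min(range(n + 1), key=lambda x: abs(
            math.asin(math.sqrt(x / n)) - math.asin(math.sqrt(x_C / n)) - target))
        trials.append(TwoArmBinaryTrial(x_E=best, n_E=n, x_C=x_C, n_C=n,
                                        trial_id=str(n)))
    res = arcsine_comparator(
        MetaAnalysisData(comparison=("e", "c"), trials=tuple(trials)))
    assert res["slope"] > 0
    assert res["p_value"] < 0.05


def test_arcsine_comparator_wls_oracle(binary_ma, rng):
    """Slope and p reproduce an independent weighted-least-squares fit
    (statsmodels WLS with the same additive heterogeneity estimate)."""
    import statsmodels.api as sm

    trials = tuple(
        TwoArmBinaryTrial(x_E=int(x), n_E=int(n), x_C=int(c), n_C=int(n),
                          trial_id=str(i))
        for i, (x, c, n) in enumerate(
            zip(rng.integers(5, 20, 10), rng.integers(8, 25, 10),
                rng.integers(30, 200, 10))))
    ma = MetaAnalysisData(comparison=("e", "c"), trials=trials)
    res = arcsine_comparator(ma)
    y = np.array([math.asin(math.sqrt(t.x_E / t.n_E))
                  - math.asin(math.sqrt(t.x_C / t.n_C)) for t in trials])
    var = np.array([1 / (4 * t.n_E) + 1 / (4 * t.n_C) for t in trials])
    X = sm.add_constant(np.sqrt(var))
    w = 1 / (var + res["tau2"])
    fit = sm.WLS(y, X, weights=w).fit()
    assert res["slope"] == pytest.approx(fit.params[1], rel=1e-10)
    # variances are known (inverse-variance weights), so the slope SE comes
    # from (X'WX)^-1 without the residual-variance rescaling OLS-style WLS
    # applies
    cov = np.linalg.inv((X.T * w) @ X)
    t_ref = fit.params[1] / math.sqrt(cov[1, 1])
    from scipy.stats import t as t_dist
    assert res["t"] == pytest.approx(t_ref, rel=1e-10)
    assert res["p_value"] == pytest.approx(
        2 * t_dist.sf(abs(t_ref), len(trials) - 2), rel=1e-8)


def test_arcsine_comparator_needs_three_trials():
    ma = MetaAnalysisData(comparison=("e", "c"), trials=(
        TwoArmBinaryTrial(x_E=5, n_E=20, x_C=9, n_C=20),
        TwoArmBinaryTrial(x_E=15, n_E=50, x_C=20, n_C=50)))
    assert not arcsine_comparator(ma)["applicable"]


def test_empirical_type1_bookkeeping():
    rate, pvals = empirical_type1(SMALL_NULL, "largest", reps=10)
    assert len(pvals) == 10
    assert rate == pytest.approx(np.mean(pvals <= 0.10))
    rate1, _ = empirical_type1(SMALL_NULL, "largest", reps=1)
    assert rate1 in (0.0, 1.0)
    with pytest.raises(ValueError):
        empirical_type1(
            ScenarioSpec(J=2, n=2, theta_j=(1.0, 1.0), tau2=0.0,
                         selection=CopasSelection(0.2, 0.5)), "largest")


def test_replicate_pvalues_deterministic_given_seed():
    a = replicate_pvalues(SMALL_NULL, methods=("fixed",), reps=8, seed=3)
    b = replicate_pvalues(SMALL_NULL, methods=("fixed",), reps=8, seed=3)
    assert np.array_equal(a["fixed"], b["fixed"])


def test_evaluate_pair_and_grid_consistency():
    alt = ScenarioSpec(J=3, n=3, theta_j=(0.8, 1.0, 0.75), tau2=0.02,
                       size_model=SizeModel(median=40, max_size=200),
                       selection=CopasSelection(0.5, 0.8), reps=40, seed=5)
    summaries = evaluate_pair(SMALL_NULL, alt, methods=("largest",), reps=25,
                              seed=5)
    s = summaries["largest"]
    assert 0 <= s.type1 <= 1 and 0 <= s.power_raw <= 1
    if 0 < s.type1 < 1:  # ratios undefined at empirical rates of 0 or 1
        assert s.lr_pos * s.type1 == pytest.approx(s.power_raw, abs=1e-12)
        assert s.lr_neg * (1 - s.type1) == pytest.approx(1 - s.power_raw, abs=1e-12)
    assert s.mc_se_type1 == pytest.approx(
        math.sqrt(s.type1 * (1 - s.type1) / 25))
    df = run_grid([("pair", SMALL_NULL, alt), ("null-only", SMALL_NULL, None)],
                  methods=("largest",), reps=10, seed=5)
    assert len(df) == 2
    assert df.loc[df.scenario == "null-only", "power_adj"].isna().all()
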