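"""Operating characteristics of the excess-significance test by simulation.

For a scenario pair (identical except that one induces reporting bias) the
module estimates the empirical type-I error rate (rejection rate without
bias), raw power (rejection rate with bias at the nominal test level),
power adjusted for type-I error (rejection rate with bias at the empirical
null critical value, so tests with differing size are comparable), and the
likelihood ratios of a positive and a negative test result.  A weighted
arcsine-regression test (funnel-plot asymmetry of arcsine-transformed risks
with an additive between-trial variance component) is provided as a
comparator for single binary meta-analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

from .bias_simulator import ScenarioSpec, simulate_biased_network
from .excess_test import binomial_excess_p, expected_significant, _observed_significant
from .plausible_effects import plausible_effect
from .significance_power import AlphaLevels
from .trial_model import MetaAnalysisData, TwoArmBinaryTrial

__all__ = [
    "PerformanceSummary",
    "replicate_pvalues",
    "empirical_type1",
    "adjusted_power",
    "likelihood_ratios",
    "arcsine_comparator",
    "evaluate_pair",
    "run_grid",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """Empirical operating characteristics of one (scenario, method) cell."""

    method_tag: str
    type1: float
    power_raw: float | None
    power_adj: float | None
    lr_pos: float | None
    lr_neg: float | None
    reps: int
    mc_se_type1: float
    mc_se_power: float | None

    def to_row(self) -> dict:
        return {
            "method": self.method_tag, "type1": self.type1,
            "power_raw": self.power_raw, "power_adj": self.power_adj,
            "lr_pos": self.lr_pos, "lr_neg": self.lr_neg,
            "reps": self.reps, "mc_se_type1": self.mc_se_type1,
            "mc_se_power": self.mc_se_power,
        }


def _mc_se(rate: float, reps: int) -> float:
    return math.sqrt(rate * (1 - rate) / reps)


def replicate_pvalues(spec: ScenarioSpec, methods=("fixed", "random", "largest"),
                      alphas: AlphaLevels = AlphaLevels(),
                      reps: int | None = None,
                      seed: int | None = None) -> dict[str, np.ndarray]:
    """Test p-values over ``reps`` simulated networks, per plausible-effect
    method.

    The per-trial significance calls are shared across methods within a
    replicate; only the plausible effect and the resulting expected counts
    differ.  Replicate r uses the derived seed ``base + r`` so any prefix of
    the replicate stream is reproducible.
    """
    reps = spec.reps if reps is None else reps
    base = spec.seed if seed is None else seed
    out = {m: np.empty(reps) for m in methods}
    for r in range(reps):
        net = simulate_biased_network(spec, seed=base + r)
        O = 0
        N = net.N
        E = {m: 0.0 for m in methods}
        for ma in net.meta_analyses:
            O += sum(_observed_significant(ma, alphas.alpha))
            for m in methods:
                theta = plausible_effect(ma, m).theta
                E_j, _ = expected_significant(ma, theta, alphas.alpha)
                E[m] += E_j
        for m in methods:
            out[m][r] = binomial_excess_p(O, min(E[m], N), N)
    return out


def empirical_type1(null_spec: ScenarioSpec, method_tag: str = "largest",
                    alphas: AlphaLevels = AlphaLevels(),
                    reps: int | None = None,
                    seed: int | None = None) -> tuple[float, np.ndarray]:
    """Rejection rate at alpha' under a no-selection scenario, with the
    replicate p-value sample retained for power adjustment."""
    if null_spec.selection is not None:
        raise ValueError("empirical_type1 requires a scenario without selection")
    pvals = replicate_pvalues(null_spec, methods=(method_tag,), alphas=alphas,
                              reps=reps, seed=seed)[method_tag]
    return float(np.mean(pvals <= alphas.alpha_prime)), pvals


def adjusted_power(null_pvalues: np.ndarray, alt_pvalues: np.ndarray,
                   alpha_prime: float = 0.10) -> float:
    """Power at the empirical null critical value: the fraction of
    alternative p-values at or below the alpha'-quantile of the null
    p-values."""
    null_pvalues = np.asarray(null_pvalues, dtype=float)
    alt_pvalues = np.asarray(alt_pvalues, dtype=float)
    if null_pvalues.size == 0 or alt_pvalues.size == 0:
        raise ValueError("both p-value samples must be non-empty")
    t_star = np.quantile(null_pvalues, alpha_prime)
    return float(np.mean(alt_pvalues <= t_star))


def likelihood_ratios(type1: float, power: float) -> tuple[float, float]:
    """LR+ = power/type1 and LR- = (1-power)/(1-type1).

    Degenerate empirical rates (type1 of exactly 0 or 1) make a ratio
    undefined; the corresponding entry is returned as +inf or nan rather
    than raising, since they can arise at small replicate counts.
    """
    lr_pos = power / type1 if type1 > 0 else math.inf
    lr_neg = (1 - power) / (1 - type1) if type1 < 1 else math.nan
    return lr_pos, lr_neg


def arcsine_comparator(ma: MetaAnalysisData) -> dict:
    """Funnel-asymmetry comparator for a single binary meta-analysis.

    Per-trial effect arcsin(sqrt(x_E/n_E)) - arcsin(sqrt(x_C/n_C)) with
    sampling variance 1/(4 n_E) + 1/(4 n_C); the effect is regressed on its
    standard error by weighted least squares with an additive between-trial
    variance estimated by method of moments, and the two-sided p-value of
    the slope (t, k-2 df) is returned.  Needs at least 3 trials.
    """
    trials = ma.trials
    if not all(isinstance(t, TwoArmBinaryTrial) for t in trials):
        raise TypeError("arcsine comparator applies to binary trials only")
    k = len(trials)
    if k < 3:
        return {"applicable": False, "k": k, "slope": math.nan, "p_value": math.nan}
    y = np.array([math.asin(math.sqrt(t.x_E / t.n_E))
                  - math.asin(math.sqrt(t.x_C / t.n_C)) for t in trials])
    var = np.array([1 / (4 * t.n_E) + 1 / (4 * t.n_C) for t in trials])
    se = np.sqrt(var)
    X = np.column_stack([np.ones(k), se])

    def wls(weights):
        XtW = X.T * weights
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ y)
        return beta, cov

    w0 = 1 / var
    beta0, cov0 = wls(w0)
    resid = y - X @ beta0
    Q = float(np.sum(w0 * resid ** 2))
    # E[Q] = (k - 2) + c * tau2 with c = tr(W) - tr((X'WX)^-1 X'W^2 X)
    c = float(np.sum(w0) - np.trace(cov0 @ ((X.T * w0 ** 2) @ X)))
    tau2 = max(0.0, (Q - (k - 2)) / c) if c > 0 else 0.0
    w = 1 / (var + tau2)
    beta, cov = wls(w)
    slope, se_slope = float(beta[1]), math.sqrt(float(cov[1, 1]))
    t_stat = slope / se_slope
    p = float(2 * t_dist.sf(abs(t_stat), k - 2))
    return {"applicable": True, "k": k, "slope": slope, "se_slope": se_slope,
            "tau2": tau2, "t": t_stat, "p_value": p}


def evaluate_pair(null_spec: ScenarioSpec, alt_spec: ScenarioSpec,
                  methods=("fixed", "random", "largest"),
                  alphas: AlphaLevels = AlphaLevels(),
                  reps: int | None = None,
                  seed: int | None = None) -> dict[str, PerformanceSummary]:
    """Full operating characteristics for a (no-bias, bias) scenario pair."""
    if null_spec.selection is not None:
        raise ValueError("null_spec must have selection=None")
    if alt_spec is not None and alt_spec.selection is None:
        raise ValueError("alt_spec must induce selection")
    reps_n = null_spec.reps if reps is None else reps
    base = null_spec.seed if seed is None else seed
    null_p = replicate_pvalues(null_spec, methods, alphas, reps=reps_n, seed=base)
    alt_p = None
    if alt_spec is not None:
        # disjoint seed block for the biased replicates
        alt_p = replicate_pvalues(alt_spec, methods, alphas, reps=reps_n,
                                  seed=base + reps_n)
    out = {}
    for m in methods:
        type1 = float(np.mean(null_p[m] <= alphas.alpha_prime))
        if alt_p is None:
            out[m] = PerformanceSummary(
                method_tag=m, type1=type1, power_raw=None, power_adj=None,
                lr_pos=None, lr_neg=None, reps=reps_n,
                mc_se_type1=_mc_se(type1, reps_n), mc_se_power=None)
            continue
        power_raw = float(np.mean(alt_p[m] <= alphas.alpha_prime))
        power_adj = adjusted_power(null_p[m], alt_p[m], alphas.alpha_prime)
        lr_pos, lr_neg = likelihood_ratios(type1, power_raw)
        out[m] = PerformanceSummary(
            method_tag=m, type1=type1, power_raw=power_raw,
            power_adj=power_adj, lr_pos=lr_pos, lr_neg=lr_neg, reps=reps_n,
            mc_se_type1=_mc_se(type1, reps_n),
            mc_se_power=_mc_se(power_raw, reps_n))
    return out


def run_grid(pairs, methods=("fixed", "random", "largest"),
             alphas: AlphaLevels = AlphaLevels(), reps: int | None = None,
             seed: int | None = None):
    """Evaluate a list of (label, null_spec, alt_spec) scenario pairs.

    ``alt_spec`` may be None for a type-I-error-only row.  Returns a pandas
    DataFrame with one row per (scenario, method).
    """
    import pandas as pd

    rows = []
    for label, null_spec, alt_spec in pairs:
        summaries = evaluate_pair(null_spec, alt_spec, methods, alphas,
                                  reps=reps, seed=seed)
        for m in methods:
            row = {"scenario": label, "J": null_spec.J, "n": null_spec.n,
                   "tau2": null_spec.tau2}
            row.update(summaries[m].to_row())
            rows.append(row)
    return pd.DataFrame(rows)
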