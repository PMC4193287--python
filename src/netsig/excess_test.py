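"""The excess-significance test for a meta-analysis and a trial network.

The observed number O of trials with nominally significant results (two-sided
alpha, default 0.05) is compared with the expected number E, the sum of the
trials' powers 1 - beta_i to detect an assumed plausible effect theta_j.
Under the null hypothesis of no reporting bias the number of significant
trials is modelled as Binomial(N, E/N); the test reports the exact one-tail
upper probability P(X >= O) and signals excess significance when it falls at
or below the test-level alpha' (default 0.10).

For a network of J meta-analyses the plausible effect of each meta-analysis
is estimated independently from its own direct evidence, and O, E, N are
summed across the network before the single binomial comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import binom

from .plausible_effects import plausible_effect
from .significance_power import (
    AlphaLevels,
    fisher_rejection_region,
    is_significant_continuous,
    is_significant_generic,
    power_binary,
    power_continuous,
    power_generic,
)
from .trial_model import (
    MetaAnalysisData,
    TrialNetwork,
    TwoArmBinaryTrial,
    TwoArmContinuousTrial,
)

__all__ = [
    "MetaAnalysisBreakdown",
    "ExcessSigResult",
    "binomial_excess_p",
    "expected_significant",
    "test_meta_analysis",
    "test_network",
]


def binomial_excess_p(O: int, E: float, N: int) -> float:
    """Exact one-tail binomial upper probability P(X >= O), X ~ Binomial(N, E/N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= O <= N:
        raise ValueError(f"need 0 <= O <= N, got O={O}, N={N}")
    if not 0 <= E <= N:
        raise ValueError(f"need 0 <= E <= N, got E={E}, N={N}")
    if O == 0:
        return 1.0
    return float(binom.sf(O - 1, N, E / N))


@dataclass(frozen=True)
class MetaAnalysisBreakdown:
    comparison: tuple[str, str]
    O_j: int
    E_j: float
    n_j: int
    theta_j: float


@dataclass(frozen=True)
class ExcessSigResult:
    """Observed vs expected significant-trial counts and the binomial p-value.

    ``P_bar`` = E/N is the common per-trial success probability of the
    binomial null model; ``signal`` is True when ``p_value <= alpha_prime``.
    """

    O: int
    E: float
    N: int
    P_bar: float
    p_value: float
    method_tag: str
    alphas: AlphaLevels
    per_ma: tuple[MetaAnalysisBreakdown, ...] = field(default=())
    per_trial_power: tuple[float, ...] = field(default=())

    @property
    def signal(self) -> bool:
        return self.p_value <= self.alphas.alpha_prime

    def to_dict(self) -> dict:
        return {
            "O": self.O, "E": self.E, "N": self.N, "P_bar": self.P_bar,
            "p_value": self.p_value, "signal": self.signal,
            "method": self.method_tag,
            "alpha": self.alphas.alpha, "alpha_prime": self.alphas.alpha_prime,
            "per_meta_analysis": [
                {"comparison": " vs ".join(filter(None, b.comparison)),
                 "O_j": b.O_j, "E_j": b.E_j, "n_j": b.n_j, "theta_j": b.theta_j}
                for b in self.per_ma],
            "per_trial_power": list(self.per_trial_power),
        }


def _clamped_control_rate(trial: TwoArmBinaryTrial) -> float:
    """Observed control event rate, kept away from the degenerate 0/1
    boundary by half an event: x_C/n_C clamped to [0.5/n_C, 1 - 0.5/n_C]."""
    lo = 0.5 / trial.n_C
    return min(max(trial.x_C / trial.n_C, lo), 1 - lo)


def _trial_power(trial, theta_j: float, alpha: float) -> float:
    if isinstance(trial, TwoArmBinaryTrial):
        return power_binary(trial.n_E, trial.n_C,
                            _clamped_control_rate(trial),
                            math.exp(theta_j), alpha)
    if isinstance(trial, TwoArmContinuousTrial):
        return power_continuous(trial.n_E, trial.n_C, theta_j, alpha)
    return power_generic(trial.se, theta_j, alpha)


def expected_significant(ma: MetaAnalysisData, theta_j: float,
                         alpha: float = 0.05) -> tuple[float, list[float]]:
    """E_j = sum of per-trial powers to detect ``theta_j`` (analysis scale:
    log odds ratio for binary meta-analyses, SMD for continuous ones).

    Every trial contributes a power, including trials that were
    non-informative for summary estimation.
    """
    powers = [_trial_power(t, theta_j, alpha) for t in ma.trials]
    return float(sum(powers)), powers


def _observed_significant(ma: MetaAnalysisData, alpha: float) -> list[bool]:
    flags = []
    for t in ma.trials:
        if isinstance(t, TwoArmBinaryTrial):
            # shares the cached rejection region with the power computation
            R = fisher_rejection_region(t.n_E, t.n_C, alpha)
            flags.append(bool(R[t.x_E, t.x_C] > 0))
        elif isinstance(t, TwoArmContinuousTrial):
            flags.append(is_significant_continuous(t, alpha))
        else:
            flags.append(is_significant_generic(t, alpha))
    return flags


def _ma_components(ma: MetaAnalysisData, method_tag: str, alphas: AlphaLevels,
                   smd: str) -> tuple[MetaAnalysisBreakdown, list[float]]:
    theta = plausible_effect(ma, method_tag, smd=smd).theta
    O_j = sum(_observed_significant(ma, alphas.alpha))
    E_j, powers = expected_significant(ma, theta, alphas.alpha)
    return MetaAnalysisBreakdown(comparison=ma.comparison, O_j=O_j, E_j=E_j,
                                 n_j=ma.n_j, theta_j=theta), powers


def _assemble(parts, powers, method_tag, alphas) -> ExcessSigResult:
    O = sum(b.O_j for b in parts)
    E = sum(b.E_j for b in parts)
    N = sum(b.n_j for b in parts)
    assert E <= N + 1e-9, "each power is <= 1, so E cannot exceed N"
    p = binomial_excess_p(O, min(E, N), N)
    return ExcessSigResult(O=O, E=E, N=N, P_bar=E / N, p_value=p,
                           method_tag=method_tag, alphas=alphas,
                           per_ma=tuple(parts), per_trial_power=tuple(powers))


def test_meta_analysis(ma: MetaAnalysisData, method_tag: str = "fixed",
                       alphas: AlphaLevels = AlphaLevels(),
                       smd: str = "d") -> ExcessSigResult:
    """Excess-significance test of a single meta-analysis."""
    part, powers = _ma_components(ma, method_tag, alphas, smd)
    return _assemble([part], powers, method_tag, alphas)


def test_network(net: TrialNetwork, method_tag: str = "fixed",
                 alphas: AlphaLevels = AlphaLevels(),
                 smd: str = "d") -> ExcessSigResult:
    """Excess-significance test of a whole network.

    Plausible effects are estimated per meta-analysis from direct evidence
    only; O, E and N are summed across the J meta-analyses and compared in a
    single one-tail binomial test.
    """
    parts, powers = [], []
    for ma in net.meta_analyses:
        part, pw = _ma_components(ma, method_tag, alphas, smd)
        parts.append(part)
        powers.extend(pw)
    return _assemble(parts, powers, method_tag, alphas)


# these are library entry points, not test cases
test_meta_analysis.__test__ = False  # type: ignore[attr-defined]
test_network.__test__ = False  # type: ignore[attr-defined]
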