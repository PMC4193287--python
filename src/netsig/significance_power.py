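"""Per-trial significance calls and power against an assumed true effect.

Binary outcomes use the two-sided Fisher exact test; continuous outcomes the
two-sided pooled-variance two-sample t-test; generic effect sizes a normal
(Wald) approximation.  Power is the probability that the same test rejects
when the data are generated under an assumed true effect: an odds ratio for
binary trials, a standardized mean difference for continuous trials, an
effect on its own scale for generic trials.

The Fisher two-sided p-value follows the minimum-likelihood convention: the
sum of probabilities, over tables with the observed margins, of every table
whose probability does not exceed that of the observed table (a relative
tolerance of 1e-7 guards ties, matching ``scipy.stats.fisher_exact``).
Binary power is computed exactly by enumerating the joint double-binomial
distribution over the cached Fisher rejection region; a seeded Monte-Carlo
fallback covers arm sizes beyond the exact limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from scipy.stats import nct, norm
from scipy.stats import t as t_dist

from .trial_model import (
    GenericEffectTrial,
    Trial,
    TwoArmBinaryTrial,
    TwoArmContinuousTrial,
)

__all__ = [
    "AlphaLevels",
    "fisher_two_sided_p",
    "fisher_rejection_region",
    "is_significant",
    "is_significant_binary",
    "is_significant_continuous",
    "is_significant_generic",
    "odds_transform",
    "power_binary",
    "power_continuous",
    "power_generic",
]

#: Relative tolerance for pmf ties in the minimum-likelihood rule.
_TIE_REL_TOL = 1e-7

#: Exact double-binomial enumeration is used while
#: (n_E + 1) * (n_C + 1) stays below this; Monte-Carlo otherwise.
EXACT_PAIR_LIMIT = 4_200_000


@dataclass(frozen=True)
class AlphaLevels:
    """Significance levels: per-trial two-sided ``alpha`` and test-level
    one-tail ``alpha_prime`` (the threshold for the excess-significance
    binomial test itself)."""

    alpha: float = 0.05
    alpha_prime: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.alpha_prime < 1):
            raise ValueError("alpha levels must lie strictly in (0, 1)")


# Growing table of log k! = gammaln(k+1), shared by the pmf helpers below.
_LOGFACT = gammaln(np.arange(2) + 1.0)


def _logfact(up_to: int) -> np.ndarray:
    global _LOGFACT
    if up_to >= _LOGFACT.size:
        _LOGFACT = gammaln(np.arange(max(up_to + 1, 2 * _LOGFACT.size)) + 1.0)
    return _LOGFACT


def _binom_pmf_vec(n: int, p: float) -> np.ndarray:
    """pmf of Binomial(n, p) over 0..n, computed in log space."""
    L = _logfact(n)
    k = np.arange(n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = (L[n] - L[k] - L[n - k]
                  + k * math.log(p) + (n - k) * math.log1p(-p))
    return np.exp(logpmf)


def odds_transform(pi_C: float, theta: float) -> float:
    """Event probability whose odds are ``theta`` times the odds of ``pi_C``."""
    if not (0 < pi_C < 1):
        raise ValueError(f"pi_C must lie in (0, 1), got {pi_C}")
    if not theta > 0:
        raise ValueError(f"theta (odds ratio) must be positive, got {theta}")
    return theta * pi_C / (1 - pi_C + theta * pi_C)


def _margin_two_sided_p(n_E: int, n_C: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every table with margins (n_E, n_C, m).

    Returns ``(ks, p)`` where ``ks`` are the possible experimental-arm event
    counts for column total ``m`` and ``p[i]`` the two-sided p-value of the
    table with x_E = ks[i].
    """
    lo, hi = max(0, m - n_C), min(n_E, m)
    ks = np.arange(lo, hi + 1)
    L = _logfact(n_E + n_C)
    logpmf = (L[n_E] - L[ks] - L[n_E - ks]
              + L[n_C] - L[m - ks] - L[n_C - m + ks]
              - (L[n_E + n_C] - L[m] - L[n_E + n_C - m]))
    pmf = np.exp(logpmf)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1 + _TIE_REL_TOL), side="right")
    p = np.minimum(csum[idx - 1], 1.0)
    return ks, p


def fisher_two_sided_p(x_E: int, n_E: int, x_C: int, n_C: int) -> float:
    """Two-sided Fisher exact p-value of the 2x2 table (minimum-likelihood rule)."""
    ks, p = _margin_two_sided_p(n_E, n_C, x_E + x_C)
    return float(p[np.searchsorted(ks, x_E)])


@lru_cache(maxsize=512)
def fisher_rejection_region(n_E: int, n_C: int, alpha: float = 0.05) -> np.ndarray:
    """Indicator matrix R with R[x_E, x_C] = 1 iff the Fisher two-sided
    p-value of the table is <= alpha.  Cached per (n_E, n_C, alpha)."""
    R = np.zeros((n_E + 1, n_C + 1), dtype=np.float32)
    for m in range(n_E + n_C + 1):
        ks, p = _margin_two_sided_p(n_E, n_C, m)
        R[ks, m - ks] = p <= alpha
    return R


def is_significant_binary(trial: TwoArmBinaryTrial, alpha: float = 0.05) -> bool:
    """Whether the two-sided Fisher exact p-value is <= alpha.

    Degenerate tables (an all-zero or all-one margin) have p = 1 and are
    never significant.
    """
    return fisher_two_sided_p(trial.x_E, trial.n_E, trial.x_C, trial.n_C) <= alpha


def _pooled_t_stat(trial: TwoArmContinuousTrial) -> tuple[float, int]:
    n_E, n_C = trial.n_E, trial.n_C
    df = n_E + n_C - 2
    sp2 = ((n_E - 1) * trial.s_E ** 2 + (n_C - 1) * trial.s_C ** 2) / df
    t = (trial.m_E - trial.m_C) / math.sqrt(sp2 * (1 / n_E + 1 / n_C))
    return t, df


def is_significant_continuous(trial: TwoArmContinuousTrial,
                              alpha: float = 0.05) -> bool:
    """Whether the two-sided pooled-variance t-test p-value is <= alpha."""
    t, df = _pooled_t_stat(trial)
    p = 2 * t_dist.sf(abs(t), df)
    return bool(p <= alpha)


def is_significant_generic(trial: GenericEffectTrial, alpha: float = 0.05) -> bool:
    """Whether the two-sided Wald p-value 2*Phi(-|estimate/se|) is <= alpha."""
    p = 2 * norm.sf(abs(trial.estimate / trial.se))
    return bool(p <= alpha)


def is_significant(trial: Trial, alpha: float = 0.05) -> bool:
    """Variant-dispatching significance call."""
    if isinstance(trial, TwoArmBinaryTrial):
        return is_significant_binary(trial, alpha)
    if isinstance(trial, TwoArmContinuousTrial):
        return is_significant_continuous(trial, alpha)
    return is_significant_generic(trial, alpha)


def power_binary(n_E: int, n_C: int, pi_C: float, theta: float,
                 alpha: float = 0.05, *, mc_reps: int = 200_000,
                 seed: int | None = None) -> float:
    """Power of the two-sided Fisher exact test to detect odds ratio ``theta``.

    Events are x_E ~ Binomial(n_E, pi_E) and x_C ~ Binomial(n_C, pi_C)
    independently, with pi_E the odds transform of pi_C by theta.  Exact
    while (n_E+1)(n_C+1) <= ``EXACT_PAIR_LIMIT`` (enumeration over the cached
    rejection region); seeded Monte-Carlo with ``mc_reps`` tables otherwise.
    """
    pi_E = odds_transform(pi_C, theta)
    if (n_E + 1) * (n_C + 1) <= EXACT_PAIR_LIMIT:
        R = fisher_rejection_region(n_E, n_C, alpha)
        pE = _binom_pmf_vec(n_E, pi_E)
        pC = _binom_pmf_vec(n_C, pi_C)
        return float(np.clip(pE @ (R @ pC), 0.0, 1.0))
    rng = np.random.default_rng(seed)
    xE = rng.binomial(n_E, pi_E, size=mc_reps)
    xC = rng.binomial(n_C, pi_C, size=mc_reps)
    hits = 0
    for m in np.unique(xE + xC):
        sel = (xE + xC) == m
        ks, p = _margin_two_sided_p(n_E, n_C, int(m))
        hits += int((p[np.searchsorted(ks, xE[sel])] <= alpha).sum())
    return hits / mc_reps


def power_continuous(n_E: int, n_C: int, g: float, alpha: float = 0.05) -> float:
    """Power of the two-sided pooled t-test against standardized mean
    difference ``g``: noncentral-t with noncentrality g*sqrt(n_E n_C/(n_E+n_C))
    and n_E+n_C-2 degrees of freedom."""
    if n_E < 2 or n_C < 2:
        raise ValueError("arm sizes must be >= 2")
    df = n_E + n_C - 2
    ncp = g * math.sqrt(n_E * n_C / (n_E + n_C))
    tcrit = t_dist.ppf(1 - alpha / 2, df)
    return float(nct.sf(tcrit, df, ncp) + nct.cdf(-tcrit, df, ncp))


def power_generic(se: float, theta: float, alpha: float = 0.05) -> float:
    """Normal-approximation power for an estimate with standard error ``se``
    against true effect ``theta``."""
    if not se > 0:
        raise ValueError("se must be positive")
    z = norm.ppf(1 - alpha / 2)
    u = abs(theta) / se
    return float(norm.cdf(u - z) + norm.cdf(-u - z))
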