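"""Plausible true-effect estimation for a meta-analysis.

The excess-significance test needs a stand-in for the unknown true effect
theta_j of each meta-analysis.  Three choices are supported: the
inverse-variance fixed-effect summary, the DerSimonian-Laird random-effects
summary, and the estimate of the largest trial.  All operate on the analysis
scale: log odds ratio for binary trials, standardized mean difference
(Cohen's d, or Hedges' g via ``smd="g"``) for continuous trials, and the
reported scale for generic trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trial_model import (
    GenericEffectTrial,
    MetaAnalysisData,
    Trial,
    TwoArmBinaryTrial,
    TwoArmContinuousTrial,
)

__all__ = [
    "PlausibleEffect",
    "EstimationError",
    "METHODS",
    "per_trial_effect",
    "fixed_effect_summary",
    "random_effects_summary",
    "largest_trial_effect",
    "plausible_effect",
]

METHODS = ("fixed", "random", "largest")


class EstimationError(ValueError):
    """No informative trial to estimate a summary from."""


@dataclass(frozen=True)
class PlausibleEffect:
    """An assumed true effect on the analysis scale.

    ``tau2_hat`` is the estimated between-trial variance (nonzero only for
    the random-effects method).
    """

    theta: float
    method_tag: str
    tau2_hat: float = 0.0

    def __post_init__(self) -> None:
        if self.method_tag not in METHODS:
            raise ValueError(f"method_tag must be one of {METHODS}")
        if self.tau2_hat < 0:
            raise ValueError("tau2_hat must be >= 0")


def per_trial_effect(trial: Trial, smd: str = "d") -> tuple[float, float] | None:
    """(estimate, SE) of one trial on its analysis scale.

    Binary trials yield the log odds ratio, with 0.5 added to every cell of
    the 2x2 table when any cell is zero; double-zero and double-full tables
    carry no comparative information and return ``None``.  Continuous trials
    yield the standardized mean difference (Cohen's d by default; ``smd="g"``
    applies the Hedges small-sample correction).  Generic trials pass
    through unchanged.
    """
    if isinstance(trial, TwoArmBinaryTrial):
        a, b = trial.x_E, trial.n_E - trial.x_E
        c, d = trial.x_C, trial.n_C - trial.x_C
        if (a == 0 and c == 0) or (b == 0 and d == 0):
            return None
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        est = math.log((a * d) / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return est, se
    if isinstance(trial, TwoArmContinuousTrial):
        n_E, n_C = trial.n_E, trial.n_C
        df = n_E + n_C - 2
        sp = math.sqrt(((n_E - 1) * trial.s_E ** 2
                        + (n_C - 1) * trial.s_C ** 2) / df)
        d_val = (trial.m_E - trial.m_C) / sp
        if smd == "g":
            d_val *= 1 - 3 / (4 * df - 1)
        elif smd != "d":
            raise ValueError("smd must be 'd' or 'g'")
        se = math.sqrt((n_E + n_C) / (n_E * n_C) + d_val ** 2 / (2 * (n_E + n_C)))
        return d_val, se
    if isinstance(trial, GenericEffectTrial):
        return trial.estimate, trial.se
    raise TypeError(f"unknown trial type {type(trial)!r}")


def _effects_matrix(ma: MetaAnalysisData, smd: str) -> tuple[np.ndarray, np.ndarray]:
    pairs = [per_trial_effect(t, smd=smd) for t in ma.trials]
    informative = [p for p in pairs if p is not None]
    if not informative:
        raise EstimationError(
            f"meta-analysis {ma.comparison}: no informative trial "
            "(all tables are double-zero or double-full)")
    arr = np.asarray(informative, dtype=float)
    return arr[:, 0], arr[:, 1]


def fixed_effect_summary(ma: MetaAnalysisData, smd: str = "d") -> PlausibleEffect:
    """Inverse-variance weighted mean of the per-trial effects."""
    y, se = _effects_matrix(ma, smd)
    w = 1.0 / se ** 2
    return PlausibleEffect(theta=float(np.sum(w * y) / np.sum(w)),
                           method_tag="fixed")


def random_effects_summary(ma: MetaAnalysisData, smd: str = "d") -> PlausibleEffect:
    """DerSimonian-Laird random-effects summary.

    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with Q the
    fixed-effect heterogeneity statistic; the summary is the weighted mean
    with weights 1/(se^2 + tau2).  With a single trial, or whenever Q <= k-1,
    tau2 truncates to zero and the result equals the fixed-effect summary.
    """
    y, se = _effects_matrix(ma, smd)
    w = 1.0 / se ** 2
    k = len(y)
    mu_fe = np.sum(w * y) / np.sum(w)
    if k == 1:
        return PlausibleEffect(theta=float(mu_fe), method_tag="random")
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se ** 2 + tau2)
    return PlausibleEffect(theta=float(np.sum(w_re * y) / np.sum(w_re)),
                           method_tag="random", tau2_hat=tau2)


def largest_trial_effect(ma: MetaAnalysisData, smd: str = "d") -> PlausibleEffect:
    """Effect estimate of the largest trial.

    "Largest" means maximum total sample size; ties (and generic trials,
    which carry no sizes) are broken by smaller standard error, then input
    order.
    """
    best = None
    for i, trial in enumerate(ma.trials):
        eff = per_trial_effect(trial, smd=smd)
        if eff is None:
            continue
        key = (-trial.total_n, eff[1], i)
        if best is None or key < best[0]:
            best = (key, eff[0])
    if best is None:
        raise EstimationError(
            f"meta-analysis {ma.comparison}: no informative trial")
    return PlausibleEffect(theta=float(best[1]), method_tag="largest")


_DISPATCH = {
    "fixed": fixed_effect_summary,
    "random": random_effects_summary,
    "largest": largest_trial_effect,
}


def plausible_effect(ma: MetaAnalysisData, method_tag: str,
                     smd: str = "d") -> PlausibleEffect:
    """Dispatch on ``method_tag`` in {'fixed', 'random', 'largest'}."""
    try:
        fn = _DISPATCH[method_tag]
    except KeyError:
        raise ValueError(f"method_tag must be one of {METHODS}, "
                         f"got {method_tag!r}") from None
    return fn(ma, smd=smd)
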