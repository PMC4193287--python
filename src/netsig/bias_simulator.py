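"""Synthetic networks of two-arm binary trials, with optional reporting bias.

Generation model
----------------
A network is J meta-analyses of n binary trials each.  Each meta-analysis j
has a true average odds ratio theta_j, either supplied directly (e.g. one of
the frozen vectors from :func:`netsig.trial_model.effect_vector_fixtures`) or
drawn once as log theta_j ~ Normal(psi, nu) (nu a variance).  Within a
meta-analysis, trial-level true effects are log theta_ij ~ Normal(log
theta_j, tau2); control event probabilities are uniform on ``rate_range``
(default 0.3-0.7); one per-arm sample size per trial (1:1 allocation) is
log-normal with configurable median and log-SD, truncated and rounded to
integers; event counts are independent binomials.

Selection models
----------------
Reporting bias is induced by generating candidate trials and keeping them
with a probability that favours impressive results, until exactly n have
been selected:

* size-and-effect (Copas-type): a latent propensity z = gamma0 + gamma1/se
  + delta decides selection (z > 0).  delta is standard normal with
  correlation rho against the sign-flipped standardized deviation of the
  trial's log odds ratio from the meta-analysis true mean, so beneficial
  (log-OR < 0) results are favoured when rho > 0.  (gamma0, gamma1) are
  solved so the marginal (rho = 0) selection probability hits configurable
  anchors at the median-size and largest-size trials' standard errors.
* p-value: significant trials (two-sided Fisher p <= alpha) are always
  selected; non-significant trials survive with probability
  ``weight_nonsig``.

Per-meta-analysis selection intensities rho_j are uniform on
[rho_min, rho_max]; presets ``MODERATE_RHO`` = (0.2, 0.5) and ``SEVERE_RHO``
= (0.5, 0.8) label moderate and severe bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .significance_power import fisher_two_sided_p, odds_transform
from .trial_model import MetaAnalysisData, TrialNetwork, TwoArmBinaryTrial

__all__ = [
    "SizeModel",
    "CopasSelection",
    "PValueSelection",
    "ScenarioSpec",
    "MODERATE_RHO",
    "SEVERE_RHO",
    "copas_gammas",
    "copas_selected",
    "pvalue_selected",
    "draw_network_effects",
    "simulate_meta_analysis",
    "simulate_network",
    "simulate_biased_network",
]

MODERATE_RHO = (0.2, 0.5)
SEVERE_RHO = (0.5, 0.8)

#: Candidate-generation cap per meta-analysis under selection.
GENERATION_CAP = 1_000_000


@dataclass(frozen=True)
class SizeModel:
    """Log-normal per-arm sample sizes, truncated and rounded to integers."""

    median: float = 50.0
    log_sd: float = 0.7
    min_size: int = 10
    max_size: int = 1000

    def __post_init__(self) -> None:
        if not (self.min_size >= 1 and self.max_size >= self.min_size):
            raise ValueError("need 1 <= min_size <= max_size")
        if self.log_sd < 0 or self.median <= 0:
            raise ValueError("median must be > 0 and log_sd >= 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        n = np.exp(rng.normal(math.log(self.median), self.log_sd, size))
        return np.clip(np.rint(n), self.min_size, self.max_size).astype(int)


@dataclass(frozen=True)
class CopasSelection:
    """Size-and-effect selection; rho_j ~ Uniform[rho_min, rho_max]."""

    rho_min: float
    rho_max: float
    p_select_median: float = 0.7
    p_select_largest: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.rho_min <= self.rho_max < 1):
            raise ValueError("need 0 <= rho_min <= rho_max < 1")
        if not (0 < self.p_select_median < self.p_select_largest < 1):
            raise ValueError("need 0 < p_select_median < p_select_largest < 1")


@dataclass(frozen=True)
class PValueSelection:
    """Select significant trials surely, others with probability weight_nonsig."""

    weight_nonsig: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.weight_nonsig <= 1:
            raise ValueError("weight_nonsig must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: network shape, effect hyper-parameters,
    between-trial variance, nuisance distributions, selection model, and
    Monte-Carlo bookkeeping."""

    J: int = 10
    n: int = 6
    psi: float = math.log(0.75)
    nu: float = 0.02
    theta_j: tuple[float, ...] | None = None  # odds-ratio scale; overrides (psi, nu)
    tau2: float = 0.08
    rate_range: tuple[float, float] = (0.3, 0.7)
    size_model: SizeModel = field(default_factory=SizeModel)
    selection: CopasSelection | PValueSelection | None = None
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1 or self.n < 1 or self.reps < 1:
            raise ValueError("J, n and reps must be >= 1")
        if self.tau2 < 0 or self.nu < 0:
            raise ValueError("tau2 and nu are variances and must be >= 0")
        lo, hi = self.rate_range
        if not (0 < lo <= hi < 1):
            raise ValueError("rate_range must be an interval inside (0, 1)")
        if self.theta_j is not None:
            if len(self.theta_j) != self.J:
                raise ValueError(
                    f"theta_j has length {len(self.theta_j)}, expected J={self.J}")
            if any(t <= 0 for t in self.theta_j):
                raise ValueError("theta_j entries are odds ratios and must be > 0")


def draw_network_effects(J: int, psi: float, nu: float,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw true average odds ratios: log theta_j ~ Normal(psi, nu), nu a variance."""
    if nu < 0:
        raise ValueError("nu is a variance and must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.exp(rng.normal(psi, math.sqrt(nu), J))


def _corrected_log_or(x_E, n_E, x_C, n_C):
    """Log odds ratio and SE with a 0.5 correction whenever any cell is zero
    (applied to degenerate tables too, so selection propensities are always
    defined)."""
    a, b, c, d = x_E, n_E - x_E, x_C, n_C - x_C
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log(a * d / (b * c)), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def copas_gammas(size_model: SizeModel = SizeModel(), rate: float = 0.5,
                 p_select_median: float = 0.7,
                 p_select_largest: float = 0.9) -> tuple[float, float]:
    """Solve (gamma0, gamma1) from the two marginal-selection anchors.

    The rho = 0 selection probability is Phi(gamma0 + gamma1/se); anchoring
    it at ``p_select_median`` for the SE of a median-size null trial and at
    ``p_select_largest`` for a largest-size trial gives a 2x2 linear system.
    """
    def se_at(n_arm: float) -> float:
        e = n_arm * rate
        return math.sqrt(2 / e + 2 / (n_arm - e))

    se_med = se_at(size_model.median)
    se_big = se_at(size_model.max_size)
    z_med, z_big = norm.ppf(p_select_median), norm.ppf(p_select_largest)
    gamma1 = (z_big - z_med) / (1 / se_big - 1 / se_med)
    gamma0 = z_med - gamma1 / se_med
    return gamma0, gamma1


def copas_selected(effect: float, se: float, rho: float, gamma0: float,
                   gamma1: float, rng: np.random.Generator,
                   ref: float = 0.0) -> bool:
    """One draw of the latent-propensity selection rule.

    ``effect`` is the trial's log odds ratio, ``ref`` the reference log
    effect its deviation is standardized against (the meta-analysis true
    mean during simulation).
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    u = (effect - ref) / se
    delta = -rho * u + math.sqrt(1 - rho * rho) * rng.standard_normal()
    return gamma0 + gamma1 / se + delta > 0


def pvalue_selected(trial_p: float, weight_nonsig: float,
                    rng: np.random.Generator, alpha: float = 0.05) -> bool:
    """Select surely if ``trial_p`` <= alpha, else with probability
    ``weight_nonsig``.  Consumes one uniform draw for non-significant trials
    only."""
    if not 0 <= weight_nonsig <= 1:
        raise ValueError("weight_nonsig must lie in [0, 1]")
    if trial_p <= alpha:
        return True
    return bool(rng.uniform() < weight_nonsig)


def _draw_trial_batch(n: int, theta: float, tau2: float, rate_range, size_model,
                      rng: np.random.Generator):
    """Draw the raw variates of ``n`` candidate trials, in a fixed order so
    that seed-matched runs with and without a pass-everything selector
    produce identical data."""
    log_theta_i = rng.normal(math.log(theta), math.sqrt(tau2), n)
    pi_C = rng.uniform(rate_range[0], rate_range[1], n)
    sizes = size_model.draw(rng, n)
    pi_E = np.array([odds_transform(p, math.exp(lt))
                     for p, lt in zip(pi_C, log_theta_i)])
    x_E = rng.binomial(sizes, pi_E)
    x_C = rng.binomial(sizes, pi_C)
    return x_E, x_C, sizes


def simulate_meta_analysis(n: int, theta: float, tau2: float,
                           rate_range=(0.3, 0.7),
                           size_model: SizeModel = SizeModel(),
                           rng: np.random.Generator | None = None,
                           seed: int | None = None,
                           comparison=("E", "C")) -> MetaAnalysisData:
    """Unbiased meta-analysis of ``n`` binary trials with true average odds
    ratio ``theta`` and between-trial variance ``tau2`` on the log scale."""
    if theta <= 0:
        raise ValueError("theta is an odds ratio and must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    x_E, x_C, sizes = _draw_trial_batch(n, theta, tau2, rate_range,
                                        size_model, rng)
    trials = tuple(
        TwoArmBinaryTrial(x_E=int(e), n_E=int(s), x_C=int(c), n_C=int(s),
                          trial_id=f"{comparison[0]}v{comparison[1]}-{i + 1}")
        for i, (e, c, s) in enumerate(zip(x_E, x_C, sizes)))
    return MetaAnalysisData(comparison=tuple(comparison), trials=trials)


def _select_meta_analysis(spec: ScenarioSpec, theta: float, rho: float,
                          gammas, rng: np.random.Generator,
                          comparison) -> MetaAnalysisData:
    """Generate candidates until ``spec.n`` survive the selection model."""
    sel = spec.selection
    kept: list[TwoArmBinaryTrial] = []
    generated = 0
    while len(kept) < spec.n:
        if generated >= GENERATION_CAP:
            raise RuntimeError(
                f"meta-analysis {comparison}: generation cap {GENERATION_CAP} "
                "exceeded before selecting enough trials")
        x_E, x_C, sizes = _draw_trial_batch(spec.n, theta, spec.tau2,
                                            spec.rate_range, spec.size_model,
                                            rng)
        generated += spec.n
        for e, c, s in zip(x_E, x_C, sizes):
            if isinstance(sel, CopasSelection):
                y, se = _corrected_log_or(int(e), int(s), int(c), int(s))
                keep = copas_selected(y, se, rho, gammas[0], gammas[1], rng,
                                      ref=math.log(theta))
            else:
                p = fisher_two_sided_p(int(e), int(s), int(c), int(s))
                keep = pvalue_selected(p, sel.weight_nonsig, rng, sel.alpha)
            if keep:
                kept.append(TwoArmBinaryTrial(
                    x_E=int(e), n_E=int(s), x_C=int(c), n_C=int(s),
                    trial_id=f"{comparison[0]}v{comparison[1]}-{len(kept) + 1}"))
                if len(kept) == spec.n:
                    break
    return MetaAnalysisData(comparison=tuple(comparison), trials=tuple(kept))


def _network_thetas(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.theta_j is not None:
        return np.asarray(spec.theta_j, dtype=float)
    return draw_network_effects(spec.J, spec.psi, spec.nu, rng=rng)


def simulate_biased_network(spec: ScenarioSpec,
                            seed: int | None = None) -> TrialNetwork:
    """Simulate one network under ``spec``; ``seed`` overrides ``spec.seed``.

    Each meta-analysis consumes an independent child RNG stream, so
    selection rejections in one meta-analysis never perturb another.  With
    ``selection=None`` this reduces exactly to unbiased generation.
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    head, *children = root.spawn(spec.J + 1)
    head_rng = np.random.default_rng(head)
    thetas = _network_thetas(spec, head_rng)
    rhos = np.zeros(spec.J)
    gammas = None
    if isinstance(spec.selection, CopasSelection):
        sel = spec.selection
        rhos = head_rng.uniform(sel.rho_min, sel.rho_max, spec.J)
        gammas = copas_gammas(spec.size_model,
                              p_select_median=sel.p_select_median,
                              p_select_largest=sel.p_select_largest)
    mas = []
    for j, child in enumerate(children):
        rng_j = np.random.default_rng(child)
        comparison = (f"T{j + 1}", "C")
        if spec.selection is None:
            mas.append(simulate_meta_analysis(
                spec.n, float(thetas[j]), spec.tau2, spec.rate_range,
                spec.size_model, rng=rng_j, comparison=comparison))
        else:
            mas.append(_select_meta_analysis(spec, float(thetas[j]),
                                             float(rhos[j]), gammas, rng_j,
                                             comparison))
    return TrialNetwork(meta_analyses=tuple(mas))


def simulate_network(spec: ScenarioSpec, seed: int | None = None) -> TrialNetwork:
    """Alias for :func:`simulate_biased_network` (the spec's ``selection``
    field decides whether any bias is induced)."""
    return simulate_biased_network(spec, seed=seed)
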