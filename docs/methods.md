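# Methods

## The excess-significance test

A meta-analysis of *n* trials yields an observed count *O* of trials whose
own hypothesis test is two-sided significant at level α, and an expected
count *E* = Σᵢ (1 − βᵢ), where 1 − βᵢ is trial *i*'s power to detect an
assumed true effect θ at the same α.  Under the null hypothesis of no
reporting bias, *O* is modelled as Binomial(*n*, *E*/*n*) and the test
reports the exact upper-tail probability P(X ≥ O), rejecting at α′.  For a
network, the counts of *J* meta-analyses are summed (each with its own
θⱼ estimated from its own direct evidence) and a single binomial
comparison is made with the average success probability P̄ = E/N.

Assumptions worth keeping in mind:

- The binomial model takes a *common* success probability across trials,
  while the true per-trial powers vary; the test is an approximation by
  construction.
- θⱼ is estimated from the very trials being tested.  Under reporting
  bias all three estimators are biased away from the null, inflating *E*,
  so the test is conservative: a signal is meaningful, its absence weak
  evidence.
- Between-trial heterogeneity and bias are partly confounded: when trial
  effects vary around θⱼ, more of them land in a detectable range than
  power-at-θⱼ predicts, which inflates the test's size when θⱼ is a
  summary estimate (see the simulation results below for how the
  largest-trial choice mitigates this).

### Defaults and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `alpha` | 0.05 | per-trial two-sided significance level |
| `alpha_prime` | 0.10 | one-tail level of the excess test itself, the usual choice for reporting-bias tests |
| `method_tag` | — | plausible effect: `fixed`, `random` (DerSimonian–Laird), or `largest` |
| `smd` | `"d"` | continuous standardization: Cohen's d; `"g"` applies the Hedges small-sample factor |

Both significance and the rejection rule count a boundary p-value as
significant (≤, not <).

## Per-trial statistics

**Binary.**  Significance is the two-sided Fisher exact test under the
minimum-likelihood convention: p = sum of probabilities, over tables with
the observed margins, of all tables no more probable than the observed one
(relative tie tolerance 1e-7; verified identical to
`scipy.stats.fisher_exact`).  Power against an odds ratio θ fixes the
control event probability at the trial's observed control rate (clamped to
[0.5/n_C, 1 − 0.5/n_C] to avoid degenerate 0/1 rates), maps it through the
odds transform π_E = θπ_C/(1 − π_C + θπ_C), and sums the joint
double-binomial probability over the Fisher rejection region.  The region
depends only on (n_E, n_C, α) and is cached, so the power computation is
*exact* for all arm sizes the package targets ((n_E+1)(n_C+1) up to
4.2×10⁶, i.e. arms of ~2000); beyond that a seeded Monte-Carlo fallback is
used.  Effect estimation uses the log odds ratio with 0.5 added to every
cell when any cell is zero; double-zero/double-full tables are
non-informative for estimation but still contribute their power to *E*.

**Continuous.**  Pooled-variance two-sample t-test (not Welch, matching
the classical SMD framework); power is the noncentral-t tail with
noncentrality g·√(n_E n_C/(n_E+n_C)) and n_E+n_C−2 df.  SE of d uses
(n_E+n_C)/(n_E n_C) + d²/(2(n_E+n_C)).

**Generic (estimate + SE).**  Wald normal approximation throughout — this
is the form in which published case-study effect sizes arrive, and no
arm-level information exists to do better.

**Plausible-effect details.**  "Largest" means maximum total sample size,
ties broken by smaller SE then input order (generic trials carry no sizes,
so precision does the ranking).  The random-effects between-trial variance
is DerSimonian–Laird with truncation at zero, under which the summary
collapses exactly to the fixed-effect one whenever Q ≤ k−1.

## The simulation framework

### What the generator emulates

Binary-outcome trial networks under a two-level random-effects model:
network-level true average odds ratios log θⱼ ~ N(ψ, ν) (or a frozen
vector; the packaged vectors are one realization per (ψ, ν, J) setting,
reused across scenarios), trial-level effects log θᵢⱼ ~ N(log θⱼ, τ²),
control event probabilities Uniform(0.3, 0.7), and log-normal per-arm
sizes (median 50, log-SD 0.7, truncated to [10, 1000], rounded).  Each
trial uses one size for both arms — 1:1 allocation, the norm for the
regulatory-style trials being emulated.  Scenario defaults (J ∈ {6, 10},
n ∈ {3, 6}, τ² ∈ {0.02, 0.08, 0.25}) bracket what large collections of
Cochrane reviews report.

Reporting bias is induced by rejection sampling until n trials survive:

- **Size-and-effect (Copas-type)** selection: latent propensity
  z = γ₀ + γ₁/se + δ, selected iff z > 0, where δ is standard normal with
  correlation ρ against the sign-flipped standardized deviation of the
  trial's log odds ratio from its meta-analysis true mean — so
  higher-precision trials and more beneficial-looking results are both
  favoured, and ρ grades the bias (per-meta-analysis ρⱼ uniform on a
  range; presets (0.2, 0.5) "moderate" and (0.5, 0.8) "severe").
  (γ₀, γ₁) solve the two anchors Φ(γ₀+γ₁/se) = 0.7 at the median-size
  trial's SE and 0.9 at the largest.  This parameterization — the
  reference effect, the anchors, the ρ ranges — is a reconstruction: it is
  stated here precisely so it can be audited and varied, and every
  constant is a named config key.
- **P-value selection**: significant trials always survive,
  non-significant ones with probability `weight_nonsig`.

What it does *not* emulate: continuous outcomes (the performance study is
binary-only), network geometry (no shared-comparator correlation, no
closed loops — effects come from a hyperdistribution, not a consistency
model), multi-arm trials, time trends, or bias mechanisms that differ
systematically across comparisons.  Passing simulation tests therefore
says nothing about, e.g., loop-inconsistent networks or very rare events
(control rates below 0.3 degrade the test's power; no test does well
there).

### Reproducibility

One `SeedSequence` per network, spawned into independent child streams per
meta-analysis, so selection rejections in one meta-analysis never shift
the random numbers of another; replicate r of a scenario uses seed
base + r, making any prefix of a run reproducible.  A pass-everything
selector is seed-matched identical to unbiased generation.

### Operating characteristics

Type-I error is the rejection rate at α′ over no-selection replicates.
Power is reported raw (at α′) and *adjusted for type-I error* — the
rejection rate at the empirical α′-quantile of the matching null p-value
sample, the standard empirical-critical-value construction, so methods
with different size are comparable.  LR⁺ = power/type-I and
LR⁻ = (1−power)/(1−type-I) summarize how a positive or negative signal
shifts the odds that bias is present; both the nominal-threshold and
adjusted rates are available, and the output table carries Monte-Carlo
standard errors √(r(1−r)/reps).  The arcsine comparator regresses
arcsin√(risk) differences on their SE with an additive method-of-moments
heterogeneity component and known-variance weights (no residual-variance
rescaling), slope tested on k−2 df; it needs ≥ 3 trials.

The packaged checks run at 2,000 replicates — enough that a rate near 0.10
carries a Monte-Carlo SE of ~0.007, and small enough that the whole suite
runs in a couple of minutes on one CPU; `ScenarioSpec.reps` defaults to
10,000 for production-scale runs.  At those settings the suite verifies,
rather than asserts from memory: near-nominal type-I error for the
largest-trial method even at τ² = 0.25; size inflation growing with τ²
for the summary-based methods (and over-conservatism at τ² = 0.02); and
the adjusted-power ordering largest ≥ fixed ≥ random under size-and-effect
selection.  The largest-trial calibration sits slightly below nominal
(≈0.08 at τ² = 0.25) under this generator — where exactly it lands is
sensitive to the trial-size distribution, which is a reconstruction
default here.

## Degenerate inputs and numerical conventions

- Empty-margin 2×2 tables: Fisher p = 1, never significant; power is still
  defined (the rejection region ignores the observed table).
- A meta-analysis whose every table is double-zero/double-full has no
  estimable effect → explicit estimation error.
- E > N is mathematically impossible (powers ≤ 1) and asserted.
- Empirical LRs at type-I rates of exactly 0 or 1 return ±inf/nan flags
  instead of raising (they occur at small replicate counts).
- O = 0 returns binomial p = 1 without computation.
- Worked-example fixtures store both the header and text trial counts of
  the case-study networks; the antipsychotic-FDA column is internally
  inconsistent as printed (an E exceeding N) and is flagged `suspect` — no
  check relies on it.

## Known limitations

- The Wald treatment of generic effect sizes ignores the t-correction a
  trial-level reanalysis would use; for the moderately sized trials of the
  case studies the difference is small.
- Copas-model constants are reconstruction defaults (see above), so
  absolute power figures should be read as orderings and trends, not
  portable numbers.
- No multi-arm support: a K-arm trial must be reduced to independent
  two-arm rows upstream, which over-counts shared control arms.
- Consistency (network-meta-analysis) estimates as plausible effects are
  out of scope; θⱼ always comes from direct evidence.
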