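# netsig

Excess-significance testing for reporting bias in meta-analyses and
networks of randomized trials.

## The problem

Trials with "positive" (statistically significant) results are more likely
to be published, and published analyses are more likely to be the
significant ones.  A body of evidence distorted this way contains *more
nominally significant trials than its own power can explain*.  `netsig`
tests for that excess — in a single pairwise meta-analysis, or jointly
across a network of *J* meta-analyses sharing one clinical question (for
example, all placebo-controlled trials of a drug class) — which is where
the test earns its keep, since any single comparison rarely has enough
trials to say anything.

## The test

For a network of *J* meta-analyses with *n<sub>j</sub>* trials each
(*N* = Σ *n<sub>j</sub>*):

- **O** — the observed number of trials with two-sided p ≤ α (default
  α = 0.05): Fisher's exact test for binary outcomes, the pooled-variance
  t-test for continuous outcomes, a Wald test for generic effect sizes.
- **E** = Σ<sub>j</sub> Σ<sub>i</sub> (1 − β<sub>ij</sub>) — the expected
  number, summing each trial's power to detect a *plausible effect*
  θ<sub>j</sub> of its meta-analysis at level α.  θ<sub>j</sub> is the
  fixed-effect summary, the DerSimonian–Laird random-effects summary, or
  the largest trial's estimate, from direct evidence only.  Binary-outcome
  power is the exact double-binomial power of Fisher's test at the trial's
  observed control event rate; continuous-outcome power uses the
  noncentral-t distribution.
- The test rejects "no excess" when the exact one-tail binomial
  probability P(X ≥ O), X ~ Binomial(N, E/N), falls at or below
  α′ = 0.10.

A signal says the body of evidence contains more significance than it
should — publication bias, selective analysis/outcome reporting, or
heterogeneity masquerading as either; the test cannot tell these apart.

The package also ships the simulation machinery to characterize the test:
a random-effects generator of binary-outcome trial networks, two selection
models for inducing reporting bias (a Copas-type latent-propensity model
driven by trial precision and effect direction, and a p-value-based
selector), and estimators of empirical type-I error, type-I-adjusted
power and likelihood ratios, plus an arcsine-regression funnel-asymmetry
comparator.

## Worked example

The O/E/N counts of the antidepressant case-study network (74 FDA-registered
trials, fixed-effect plausible effects) through the direct O/E/N entry
point:

```sh
$ netsig test --from-oe 38 34.5 74
{
  "from_oe": {
    "O": 38,
    "E": 34.5,
    "N": 74,
    "P_bar": 0.46621621621621623,
    "p_value": 0.24195603313821512,
    "signal": false
  }
}
```

38 significant trials were observed where 34.5 were expected; the one-tail
binomial p-value 0.24 is above α′ = 0.10, so the complete FDA registry
shows no signal of excess significance (the matching *published* subset of
the same network does).

From trial-level data the same test runs end to end.  `netsig fixtures`
writes a seeded synthetic demo network; each meta-analysis gets its own
plausible effect and the per-comparison breakdown is reported:

```sh
$ netsig fixtures --out-dir demo --seed 7
$ netsig test --input demo/demo_network.csv --method fixed
{
  "fixed": {
    "O": 2,
    "E": 1.5905742379309102,
    "N": 20,
    "P_bar": 0.0795287118965455,
    "p_value": 0.4799450123191885,
    "signal": false,
    ...
    "per_meta_analysis": [
      {"comparison": "T1 vs C", "O_j": 0, "E_j": 0.1179202351995728,
       "n_j": 5, "theta_j": 0.09711357607669156},
      ...
```

The same computations are available as a library:

```python
import netsig as ns

net = ns.read_network("trials.csv")
res = ns.test_network(net, method_tag="largest")
print(res.O, res.E, res.p_value, res.signal)
```

Scenario simulation and performance evaluation are driven by YAML configs
through `netsig simulate` and `netsig evaluate` (see `docs/methods.md` for
the generation model and its defaults).

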