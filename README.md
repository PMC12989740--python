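# effectsim

Simulation-based planning of multi-group exploratory experiments.

Exploratory animal experiments routinely involve many experimental
groups with small group-wise sample sizes, and the "most interesting"
effect — the pairwise comparison with the smallest p-value — is selected
after seeing the data. Even when type-I error is controlled, this
selection systematically exaggerates the reported effect size (the
winner's curse): under the global null the distribution of selected
estimates is bimodal with essentially no mass at the true value, and the
nominal 95% confidence interval loses its coverage. `effectsim` is a
planning tool for biostatisticians and ethics-committee reviewers that
quantifies this design-induced estimation error by Monte-Carlo
simulation, compares candidate designs at a fixed total animal budget,
and classifies them with a traffic-light scheme.

## The model

An experiment has `k` groups with true means `μ₁…μ_k`, common scale
`σ`, and `n` animals per group (normal outcomes by default; lognormal
and Cauchy location-scale families are supported). For a set of `J`
pairwise comparisons with effects `δⱼ = μⱼ₁ − μⱼ₂`, each comparison is
analyzed by Welch's t-test and the design reports the effect with the
smallest (optionally multiplicity-adjusted) p-value,
`j* = argminⱼ pⱼ`. The quality of the reported estimate `δ̂` is measured
by its mean squared error against the true effect of the selected pair,
`MSE(δ̂) = E[(δ̂ − δⱼ*)²]`, together with interval coverage, average
interval length, and the rejection rate.

Four designs are compared at the same total budget `n·k`:

* **standard** — single stage, report the selected Welch estimate as is;
* **repeat-and-pool** — a screening stage with
  `n₁ = ⌊n·k/(k+2)⌋` per group selects the best pair, a confirmation
  stage adds `n₂ = ⌊(n·k − n₁·k)/2⌋` fresh animals per selected group,
  and both stages are naively concatenated (a common but statistically
  flawed practice);
* **repeat-and-replace** — same two stages, but only stage-2 data enter
  the estimate;
* **Bayesian pooling** — stage-2 data are analyzed under a robust
  two-component mixture prior
  `δ ~ ω·t(ν, δ₁, σ₁) + (1−ω)·t(3, 0, σ₀)`, where `δ₁`, `σ₁` and `ν`
  are the stage-1 estimate, its standard error and its Welch degrees of
  freedom; the posterior mean is the estimate and the 2.5%/97.5%
  posterior quantiles form the interval. The heavy tails make the prior
  robust: under prior-data conflict the informative component is
  automatically down-weighted.

Ten p-value adjustments are available (Bonferroni, Holm, Hochberg,
Hommel, Benjamini-Hochberg, Dunnett and step-down Dunnett, Tukey HSD and
step-down Tukey, Shaffer S2). A design's null-hypothesis MSE is rated
GREEN / YELLOW / RED against the simulated two-group (unbiased) and
three-group reference designs at the same `n`, each boundary carrying a
5% margin.

## Worked example

```python
from effectsim import make_design, simulate, traffic_light_table

oc10 = simulate(make_design("standard", k=10, n=12, dmax=0.0),
                n_reps=10_000, master_seed=301, store=False)
oc2 = simulate(make_design("standard", k=2, n=12, dmax=0.0),
               n_reps=10_000, master_seed=302, store=False)
print(f"MSE k=10: {oc10.mse:.3f}  MSE k=2: {oc2.mse:.3f} "
      f"ratio: {oc10.mse / oc2.mse:.2f}")
```

prints

```
MSE k=10: 0.775  MSE k=2: 0.165 ratio: 4.69
```

selecting the strongest of the 45 pairwise effects among 10 groups
inflates the estimation error more than fourfold over a plain two-group
comparison, even though nothing is "wrong" with any individual test.
Rating designs against the references:

```python
table = traffic_light_table(designs=["standard", "bayes_pool"],
                            k_values=range(2, 11), n=12,
                            n_reps=2000, seed=501)
print(table[table.k.isin([2, 6, 10])][["design", "k", "relative_mse", "label"]])
```

```
        design   k  relative_mse  label
0     standard   2      0.981485  GREEN
4     standard   6      3.400491    RED
8     standard  10      4.746160    RED
9   bayes_pool   2      0.801290  GREEN
13  bayes_pool   6      0.721324  GREEN
17  bayes_pool  10      0.691360  GREEN
```

The standard design leaves the acceptable zone already at moderate group
counts, while two-stage Bayesian pooling stays GREEN throughout — it
estimates better than the unbiased two-group reference at the same
animal budget.

A CLI wraps the same functionality (`effectsim run config.yaml`,
`effectsim validate`, `effectsim traffic-light`, `effectsim plot`); see
`effectsim --help`.

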