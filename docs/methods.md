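# Methods

## Scope and model

`effectsim` simulates the operating characteristics of multi-group
experimental designs whose reported result is the *selected* strongest
pairwise effect. The data model is a one-way layout: `k` groups,
group-wise sample size `n`, outcomes drawn i.i.d. from a location-scale
family (normal, lognormal, Cauchy) with common scale. The canonical
scenarios have all group means at 0 except at most one, set to the
maximal mean difference `dmax ∈ {0, 1, 2}`; `dmax = 0` is the global
null. For the lognormal family the location/scale parameters refer to
the underlying normal on the log scale, and for all non-normal families
effects are defined as differences of *location parameters* — this keeps
the estimand well defined for Cauchy outcomes, whose mean does not
exist. These are conventions of this package: the study grid itself is
normal throughout.

Each comparison is analyzed with Welch's t-test (plain mean difference,
standard error `√(s₁²/n₁ + s₂²/n₂)`, Welch–Satterthwaite df). Selection
is `argmin p` over the comparison set, with ties broken by raw p-value
and then by comparison index so that any monotone p-value adjustment
leaves the selection unchanged and runs are reproducible. Estimation
error is always measured against the true effect of the *selected* pair,
never against `dmax`; the replicate-level `true_delta` is exposed so
users can recompute the alternative convention if they want it.

## Designs and budget accounting

The total budget is `n·k` animals. Two-stage designs screen with
`n₁ = ⌊n·k/(k+2)⌋` per group and confirm the selected pair with
`n₂ = ⌊(n·k − n₁·k)/2⌋` fresh animals per group; both floors mean the
consumed budget can fall slightly below `n·k`, and `n₂` is *not*
monotone in `k`. This rounding-induced non-monotonicity propagates into
the MSE of every two-stage design and is deliberate, not a defect.
Allocations with `n₁ < 2` or `n₂ < 2` are rejected before any data are
drawn. Stage-1 selection uses raw Welch p-values (monotone adjustments
cannot change the ranking of a screening stage).

Design-specific estimation:

* *repeat-and-pool* concatenates stage-1 and stage-2 samples of the
  selected pair and runs Welch on the pooled samples. This reproduces
  the common flawed practice of pooling data with different selection
  histories; its bias is the point, so no correction is applied.
* *repeat-and-replace* runs Welch on stage-2 data alone.
* *Bayesian pooling* builds the mixture prior from the stage-1 Welch
  summary of the selected pair and combines it with the stage-2 data
  (below).

"Rejection" for the frequentist two-stage designs is final-analysis
Welch `p < α` without further multiplicity adjustment (selection already
happened); for the Bayesian design it is the 95% credible interval
excluding 0 — the natural Bayesian analogue, chosen because no rejection
rule is otherwise implied.

## Multiplicity adjustments

All ten procedures return adjusted p-values (the smallest level at which
the step-wise rule rejects), never modified estimates or intervals.
Bonferroni, Holm, Hochberg, Hommel and Benjamini–Hochberg are applied to
Welch p-values and delegate to `statsmodels`. The Dunnett, Tukey and
Shaffer-S2 families require the one-way pooled-variance t statistics
(common df `N − k`) that their distribution theory assumes, so the
package computes those internally when such a method is configured; raw
p-values are then also taken from the pooled statistic for coherence.
This pooled-vs-Welch split is a deliberate resolution of the tension
between Welch-based per-comparison analysis and classical multiple
comparison theory.

Dunnett probabilities `P(max|T| > t)` exploit the product-form
correlation of many-to-one contrasts (`ρᵢⱼ = λᵢλⱼ`,
`λᵢ = 1/√(1 + n₀/nᵢ)`; `ρ = 1/2` at equal n): conditioning on the shared
control variate and the pooled scale reduces the orthant probability to
a smooth double integral, evaluated with 96-point Gauss–Legendre rules
in each dimension. This is deterministic (unlike randomized-QMC
multivariate-t routines) with absolute error well below the 1e-4
tolerance recorded in run metadata. Tukey probabilities use scipy's
studentized-range distribution. Because both tails are expensive per
evaluation and Monte-Carlo loops evaluate the same configuration
thousands of times, each (configuration, df) pair is tabulated once on a
fixed |t| grid and interpolated monotonically; interpolation error is
orders of magnitude below the stated tolerance.

Step-down variants follow closed testing: hypotheses ordered by
decreasing |t|, the i-th tested in the max-|T| (or range) distribution
of the comparisons not yet rejected, adjusted p-values monotonized along
the order. For Tukey the range parameter at step `i` is the largest
number of means that can still be jointly equal after `i − 1`
rejections, computed from a worst-case vertex-cover bound on the
rejection graph (Shaffer-style truncation). Shaffer's S2 uses the
attainable counts of simultaneously true pairwise hypotheses,
`{Σⱼ C(mⱼ, 2)}` over integer partitions `(m₁, m₂, …)` of `k`, as
Bonferroni multipliers in a Holm-type step-down. The step-down outputs
are verified in the tests against explicit enumeration of all
intersection hypotheses on small families.

Hommel's procedure is implemented as the standard algorithm (via
statsmodels) and checked against a brute-force closed-testing oracle
with Simes local tests rather than against any transcribed formula.

## The robust mixture-prior estimator

The stage-2 analysis model is the linear model
`yᵢ ~ N(α + δxᵢ, σ)` with group indicator `xᵢ ∈ {0, 1}`. The prior on
the effect is

```
δ ~ ω · t(ν, δ₁, σ₁) + (1 − ω) · t(3, 0, σ₀)
```

with `δ₁` the stage-1 estimate, `σ₁` its standard error, `ν` the stage-1
Welch df, and `σ₀ = σ₁` unless overridden (σ₀ is only meaningful
relative to σ₁). The skeptical component's df is fixed at 3: heavy
enough tails to avoid strong shrinkage while still centering mass at the
null. The default weight is `ω = 0.5`; `ω = 1` is full borrowing,
`ω = 0` ignores stage 1 entirely. The mixture is over `δ` only — `σ` is
shared between components.

Two backends compute the posterior:

* **quadrature** (simulation default): the stage-2 likelihood in `δ` is
  profiled to a `t(df₂, δ̂₂, se₂)` density and the 1-D posterior is
  integrated by trapezoid on a non-uniform grid formed as the union of
  the three component supports (each center ± 10 scales, 601 points
  each) — a single uniform grid cannot resolve components of very
  different scales. The grid is midpoint-refined until the posterior
  mean moves by less than 1e-4. Quantiles come from monotone
  interpolation of the normalized cumulative grid; the posterior weight
  of the informative component is the ratio of its integrated
  contribution to the total mass. Against a brute-force Riemann sum the
  mean agrees to ~1e-9.
* **mcmc**: emcee ensemble sampling of `(α, δ, log σ)` with the mixture
  prior on δ, an improper flat prior on α and a half-t(3) prior on σ
  scaled to the empirical stage-2 standard deviation — vague enough not
  to compete with the data at any feasible `n₂`. 32 walkers, 2500 steps,
  500 discarded; the t log-densities are written in closed form because
  the sampler's cost is dominated by the prior evaluation otherwise.
  Acceptance fraction, integrated autocorrelation time and a
  Monte-Carlo standard error of the posterior mean are reported, and a
  `converged` flag is set rather than failing silently.

The full-scale simulation engine uses the quadrature backend: one
posterior costs ~1.5 ms, so a 2,000-replicate Bayesian design cell runs
in seconds, whereas MCMC at the same scale would take hours. MCMC is
retained for spot-checking the profile-likelihood approximation; the
two agree within chain Monte-Carlo error plus a small (≈ 0.01 in effect
units) approximation slack on seeded batteries.

## Monte-Carlo engine and reproducibility

One master seed per run; per-replicate generators are spawned through
`numpy.random.SeedSequence`, so results are a pure function of
(design, n_reps, master_seed) and any single replicate can be reproduced
in isolation. Aggregates (MSE, coverage, average length, rejection rate)
carry the Monte-Carlo standard error of the MSE because traffic-light
boundaries are decided on noisy estimates. Replicate-level estimates,
p-values and intervals are stored by default (so estimate-distribution
and sorted-interval figures can be regenerated) and can be dropped for
memory-lean grid runs. Paired single-stage/two-stage comparisons reuse
seeds but necessarily consume different stream positions, so claimed
orderings are assessed with MC-error bands rather than replicate-paired
differences.

## Traffic-light classification

The candidate's null-scenario MSE is divided by the simulated MSE of the
unadjusted two-group standard design at the same `n` (the unbiased
reference). GREEN requires this ratio ≤ 1.05; YELLOW requires it to be
at most the three-group reference's ratio, multiplied by the same 1.05
margin (the margin is applied multiplicatively to both boundaries, a
choice recorded here and in output metadata); anything larger is RED.
References are re-simulated with dedicated seeds rather than cached, so
the classifier is self-contained at any `n`; their MC standard errors
are reported with the labels. Classification is defined under the null —
where selection bias is worst — and can be applied to
alternative-scenario MSEs as an explicit opt-in. Labels for two-stage
designs need not be monotone in `k` (the allocation rounding above);
this is expected behavior.

## Simulation sizes used in tests and the acceptance script

Worked-example arithmetic is exact. The two-group analytic anchors
(MSE = 2σ²/n, ~95% coverage) and the k=10 vs k=2 inflation ratio use
10,000 replicates; the per-design comparison and the traffic-light grid
use 2,000 replicates per cell, which keeps every claimed ordering
several MC standard errors wide while the full run stays at desk scale.
The exact second moment of the unselected two-group mean difference is
2σ²/n (the inflation factor df/(df−2) applies to the t *statistic*, not
to the mean difference, and is therefore not part of the anchor).

## What the generator emulates — and what it does not

The synthetic worlds are i.i.d. location-scale samples with at most one
nonzero group mean. Real animal experiments add litter/cage clustering,
repeated measures, unequal variances across groups, multiple endpoints,
and drift between stages; none of these are modeled, so passing tests
demonstrate correctness of the design comparison under the stated model,
not robustness of any design to those complications. Stage 2 reuses the
scenario's true parameters (no drift). Non-normal families are provided
for sensitivity analysis, but the reported study grid is normal.

## Known limitations

* Two stages only; no interim stopping, shared controls, or replication
  across experiments.
* Shaffer S2 uses the partition-based attainable-cardinality sequence
  (independent of *which* hypotheses were rejected); the fully
  rejection-aware variant would be slightly sharper in some branches.
* The Dunnett quadrature assumes the product-correlation structure of
  many-to-one contrasts; arbitrary contrast correlation matrices are out
  of scope.
* The quadrature backend relies on the t-profile approximation of the
  stage-2 likelihood; at very small n₂ (≤ 3) the full MCMC model is the
  safer reference.
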