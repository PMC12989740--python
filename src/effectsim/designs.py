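"""The four experimental designs, executed one replicate at a time.

All designs spend (at most) the same total animal budget n*k:

* ``standard`` — single stage, k groups of n; the comparison with the
  smallest (possibly adjusted) p-value is selected and reported as is.
* ``repeat_pool`` — two stages; the selected pair is re-run and the two
  stages' samples are naively concatenated for estimation.  This
  deliberately reproduces the statistically flawed but common practice
  of pooling data with different selection histories.
* ``repeat_replace`` — two stages; only the fresh stage-2 data enter the
  estimate, eliminating selection bias at the price of variance.
* ``bayes_pool`` — two stages; stage-1 summaries form the robust
  mixture prior, stage-2 data the likelihood, and the posterior mean /
  credible interval are reported.

Stage-wise sample sizes derive from the total budget: n1 = floor(n*k /
(k+2)) per group in stage 1, and the remainder n2 = floor((n*k - n1*k)/2)
per selected group in stage 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datagen import GroupSample, ScenarioSpec, draw_experiment
from .mixture_prior import build_prior, posterior_from_summary
from .multiplicity import AdjustmentContext, adjust, pooled_stats, _TSTAT_METHODS
from .pairwise import (
    ComparisonSet,
    PairwiseStat,
    SelectionOutcome,
    select_strongest,
    welch_stat,
    welch_stats,
)

KINDS = ("standard", "repeat_pool", "repeat_replace", "bayes_pool")
TWO_STAGE_KINDS = ("repeat_pool", "repeat_replace", "bayes_pool")


class InfeasibleDesignError(ValueError):
    """Raised when the stage-wise allocation violates minimum group sizes."""


@dataclass(frozen=True)
class StageAllocation:
    """Stage-wise group sample sizes of a two-stage design."""

    n1: int
    n2: int
    total_budget: int

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise InfeasibleDesignError(
                f"infeasible allocation: n1={self.n1}, n2={self.n2} (both must be >= 2)"
            )

def allocate_stages(k: int, n: int) -> StageAllocation:
    """Split the single-stage budget n*k across two stages.

    n1 = floor(n*k / (k+2)) animals per group for all k screening
    groups; n2 = floor((n*k - n1*k) / 2) per group for the two groups
    carried into the confirmation stage.  Rounding makes n2
    non-monotone in k, which propagates into the operating
    characteristics of every two-stage design.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    total = n * k
    n1 = total // (k + 2)
    n2 = (total - n1 * k) // 2
    return StageAllocation(n1=n1, n2=n2, total_budget=total)


def animals_used(alloc: StageAllocation, k: int) -> int:
    return alloc.n1 * k + alloc.n2 * 2


@dataclass
class DesignSpec:
    """A fully specified design: scenario, comparisons, analysis rules."""

    kind: str
    scenario: ScenarioSpec
    comparisons: ComparisonSet
    adjustment: AdjustmentContext | None = None
    omega: float = 0.5
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "bayes_pool" and not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")
        if self.kind in TWO_STAGE_KINDS:
            # fail fast on infeasible allocations, before any draw
            self.allocation  # noqa: B018

    @property
    def allocation(self) -> StageAllocation:
        if self.kind not in TWO_STAGE_KINDS:
            raise ValueError("single-stage designs have no stage allocation")
        return allocate_stages(self.scenario.k, self.scenario.n_per_group)

    @property
    def alpha(self) -> float:
        return self.adjustment.alpha if self.adjustment is not None else 0.05


@dataclass
class ReplicateResult:
    """Outcome of one simulated experiment."""

    selected_pair: tuple[int, int]
    estimate: float
    interval: tuple[float, float]
    true_delta: float
    p_final: float | None = None
    rejected: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def squared_error(self) -> float:
        return (self.estimate - self.true_delta) ** 2

    @property
    def covered(self) -> bool:
        return self.interval[0] <= self.true_delta <= self.interval[1]

    @property
    def interval_length(self) -> float:
        return self.interval[1] - self.interval[0]


def _apply_adjustment(
    stats_list: list[PairwiseStat],
    samples: list[GroupSample],
    ctx: AdjustmentContext | None,
) -> None:
    """Attach adjusted p-values in place, if an adjustment is configured."""
    if ctx is None or ctx.method == "none":
        return
    p_raw = [s.p_raw for s in stats_list]
    if ctx.method in _TSTAT_METHODS:
        t, df = pooled_stats(samples, ctx.comparison_set)
        ctx.pooled_df = df
        ctx.per_group_n = tuple(
            s.n for s in sorted(samples, key=lambda g: g.group_index)
        )
        # raw p recomputed from the pooled statistic for coherence
        p_raw = np.minimum(2.0 * sps.t.sf(np.abs(t), df), 1.0)
        adj = adjust(p_raw, ctx, t_stats=t)
    else:
        adj = adjust(p_raw, ctx)
    for s, pa in zip(stats_list, adj):
        s.p_adj = float(pa)


def run_standard(spec: DesignSpec, rng: np.random.Generator) -> ReplicateResult:
    """One replicate of the single-stage standard design."""
    if spec.kind != "standard":
        raise ValueError(f"run_standard got kind={spec.kind!r}")
    samples = draw_experiment(spec.scenario, rng)
    stats_list = welch_stats(samples, spec.comparisons)
    _apply_adjustment(stats_list, samples, spec.adjustment)
    sel = select_strongest(stats_list, spec.scenario, level=spec.level)
    return ReplicateResult(
        selected_pair=sel.stat.pair,
        estimate=sel.stat.estimate,
        interval=sel.interval,
        true_delta=sel.true_delta,
        p_final=sel.stat.p,
        rejected=sel.stat.p < spec.alpha,
    )


def _stage1_select(
    spec: DesignSpec, rng: np.random.Generator
) -> tuple[SelectionOutcome, dict[int, GroupSample]]:
    alloc = spec.allocation
    samples = draw_experiment(spec.scenario, rng, n_per_group=alloc.n1)
    stats_list = welch_stats(samples, spec.comparisons)
    # selection always on raw Welch p-values: monotone adjustments cannot
    # change the ranking, and stage 1 is a pure screening step
    sel = select_strongest(stats_list, spec.scenario, level=spec.level)
    return sel, {s.group_index: s for s in samples}


def run_two_stage(spec: DesignSpec, rng: np.random.Generator) -> ReplicateResult:
    """One replicate of a two-stage design (pool, replace, or Bayesian)."""
    if spec.kind not in TWO_STAGE_KINDS:
        raise ValueError(f"run_two_stage got kind={spec.kind!r}")
    alloc = spec.allocation  # raises before any draw if infeasible
    sel, stage1 = _stage1_select(spec, rng)
    ja, jb = sel.stat.pair
    fresh = draw_experiment(
        spec.scenario, rng, n_per_group=alloc.n2, groups=(ja, jb)
    )
    a2, b2 = fresh[0], fresh[1]

    if spec.kind == "repeat_pool":
        a = GroupSample(ja, np.concatenate([stage1[ja].values, a2.values]))
        b = GroupSample(jb, np.concatenate([stage1[jb].values, b2.values]))
        final = welch_stat(a, b)
    elif spec.kind == "repeat_replace":
        final = welch_stat(a2, b2)
    else:  # bayes_pool
        prior = build_prior(sel.stat, omega=spec.omega)
        s2 = welch_stat(a2, b2)
        post = posterior_from_summary(prior, s2.estimate, s2.se, s2.df)
        rejected = not (post.ci[0] <= 0.0 <= post.ci[1])
        return ReplicateResult(
            selected_pair=(ja, jb),
            estimate=post.mean,
            interval=post.ci,
            true_delta=sel.true_delta,
            p_final=None,
            rejected=rejected,
            extras={"post_weight_informative": post.post_weight_informative},
        )

    tcrit = sps.t.ppf(0.5 + spec.level / 2.0, final.df)
    interval = (final.estimate - tcrit * final.se, final.estimate + tcrit * final.se)
    return ReplicateResult(
        selected_pair=(ja, jb),
        estimate=final.estimate,
        interval=interval,
        true_delta=sel.true_delta,
        p_final=final.p_raw,
        rejected=final.p_raw < spec.alpha,
    )


def run_replicate(spec: DesignSpec, rng: np.random.Generator) -> ReplicateResult:
    """Dispatch one replicate to the design's runner."""
    if spec.kind == "standard":
        return run_standard(spec, rng)
    return run_two_stage(spec, rng)
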