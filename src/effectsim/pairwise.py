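"""Pairwise comparisons, Welch statistics, and selection of the strongest effect.

The exploratory "standard design" reports the effect with the smallest
p-value among a predefined set of J pairwise comparisons.  This module
enumerates comparison sets (all-pairwise, many-to-one, or custom),
computes per-comparison Welch two-sample statistics, and performs the
argmin-p selection that induces the winner's-curse bias studied by the
rest of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datagen import GroupSample, ScenarioSpec

MODES = ("all_pairwise", "many_to_one", "custom")


@dataclass(frozen=True)
class ComparisonSet:
    """An ordered set of (j1, j2) group-index pairs (1-based)."""

    pairs: tuple[tuple[int, int], ...]
    mode: str = "custom"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        seen = set()
        for j1, j2 in self.pairs:
            if j1 == j2:
                raise ValueError(f"pair ({j1}, {j2}) compares a group to itself")
            if (j1, j2) in seen:
                raise ValueError(f"duplicate pair ({j1}, {j2})")
            seen.add((j1, j2))

    @property
    def size(self) -> int:
        """Number of comparisons J."""
        return len(self.pairs)


def enumerate_pairs(
    k: int,
    mode: str = "all_pairwise",
    control: int | None = None,
    custom: Iterable[tuple[int, int]] | None = None,
) -> ComparisonSet:
    """Enumerate the comparisons of interest for a k-group experiment.

    ``all_pairwise`` yields all k(k-1)/2 unordered pairs as (j1, j2) with
    j1 > j2 (each non-control group minus the lower-indexed one);
    ``many_to_one`` yields the k-1 pairs (j, control); ``custom`` takes
    the pairs verbatim.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if mode == "all_pairwise":
        if control is not None or custom is not None:
            raise ValueError("all_pairwise takes neither control nor custom")
        pairs = tuple(
            (j1, j2) for j2 in range(1, k + 1) for j1 in range(j2 + 1, k + 1)
        )
    elif mode == "many_to_one":
        if control is None:
            raise ValueError("many_to_one requires a control group index")
        if not 1 <= control <= k:
            raise ValueError(f"control must be in 1..{k}, got {control}")
        if custom is not None:
            raise ValueError("many_to_one does not take custom pairs")
        pairs = tuple((j, control) for j in range(1, k + 1) if j != control)
    elif mode == "custom":
        if custom is None:
            raise ValueError("custom mode requires explicit pairs")
        pairs = tuple((int(a), int(b)) for a, b in custom)
        for j1, j2 in pairs:
            if not (1 <= j1 <= k and 1 <= j2 <= k):
                raise ValueError(f"pair ({j1}, {j2}) references a group > k={k}")
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return ComparisonSet(pairs=pairs, mode=mode)


def count_factorial_groups(levels: Sequence[int]) -> int:
    """Number of distinct groups in a fully crossed factorial layout.

    E.g. genotype x sex x age x treatment x endpoint with levels
    (2, 2, 3, 2, 3) gives 72 groups, each requiring separate animals.
    """
    if not levels:
        raise ValueError("levels must be nonempty")
    if any(int(l) < 1 for l in levels):
        raise ValueError("factor levels must be positive integers")
    return int(math.prod(int(l) for l in levels))


@dataclass
class PairwiseStat:
    """Welch two-sample statistic for one comparison."""

    pair: tuple[int, int]
    estimate: float
    se: float
    df: float
    t: float
    p_raw: float
    p_adj: float | None = None

    @property
    def p(self) -> float:
        """Adjusted p-value when available, else the raw one."""
        return self.p_raw if self.p_adj is None else self.p_adj


@dataclass
class SelectionOutcome:
    """The selected "most interesting" comparison j* = argmin p."""

    index: int  # position in the stats list
    stat: PairwiseStat
    interval: tuple[float, float]
    true_delta: float
    level: float = 0.95

    @property
    def squared_error(self) -> float:
        return (self.stat.estimate - self.true_delta) ** 2


def _welch_from_moments(
    mean_a: float, var_a: float, na: int, mean_b: float, var_b: float, nb: int
) -> tuple[float, float, float, float, float]:
    """Welch statistic from sample means/variances (ddof=1 variances)."""
    va, vb = var_a / na, var_b / nb
    se2 = va + vb
    if se2 <= 0:
        raise ValueError("degenerate input: both groups have zero variance")
    estimate = mean_a - mean_b
    se = math.sqrt(se2)
    df = se2**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    t = estimate / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return estimate, se, df, t, min(p, 1.0)


def welch_stat(a: GroupSample, b: GroupSample) -> PairwiseStat:
    """Welch's t-test of group a minus group b (unequal variances).

    The estimate is the plain mean difference; the standard error is
    sqrt(s_a^2/n_a + s_b^2/n_b) with Welch-Satterthwaite degrees of
    freedom, and the p-value is the two-sided t tail probability.
    """
    va = float(np.var(a.values, ddof=1))
    vb = float(np.var(b.values, ddof=1))
    estimate, se, df, t, p = _welch_from_moments(
        float(np.mean(a.values)), va, a.n, float(np.mean(b.values)), vb, b.n
    )
    return PairwiseStat(
        pair=(a.group_index, b.group_index),
        estimate=estimate,
        se=se,
        df=df,
        t=t,
        p_raw=p,
    )


def welch_stats(
    samples: Sequence[GroupSample], comparisons: ComparisonSet
) -> list[PairwiseStat]:
    """Welch statistics for every pair in ``comparisons``.

    ``samples`` are matched to pairs by their 1-based ``group_index``.
    Vectorized over comparisons via the group moments.
    """
    by_index = {s.group_index: s for s in samples}
    means = {g: float(np.mean(s.values)) for g, s in by_index.items()}
    vars_ = {g: float(np.var(s.values, ddof=1)) for g, s in by_index.items()}
    ns = {g: s.n for g, s in by_index.items()}
    out = []
    for j1, j2 in comparisons.pairs:
        estimate, se, df, t, p = _welch_from_moments(
            means[j1], vars_[j1], ns[j1], means[j2], vars_[j2], ns[j2]
        )
        out.append(
            PairwiseStat(pair=(j1, j2), estimate=estimate, se=se, df=df, t=t, p_raw=p)
        )
    return out


def select_strongest(
    stats_list: Sequence[PairwiseStat],
    scenario: ScenarioSpec,
    level: float = 0.95,
) -> SelectionOutcome:
    """Select the comparison with the smallest p-value.

    Uses adjusted p-values when present, raw Welch p-values otherwise
    (any monotone adjustment leaves the ranking unchanged).  Ties break
    to the lowest index for reproducibility.  The reported interval is
    the unadjusted Welch interval of the selected comparison, and
    ``true_delta`` is the true effect of that pair under ``scenario``.
    """
    if not stats_list:
        raise ValueError("stats_list must be nonempty")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    # ties in adjusted p (e.g. several values clipped at 1) break by raw p,
    # then by index, so selection coincides with raw-p selection under any
    # monotone adjustment and stays deterministic
    index = min(
        range(len(stats_list)),
        key=lambda i: (stats_list[i].p, stats_list[i].p_raw, i),
    )
    sel = stats_list[index]
    tcrit = stats.t.ppf(0.5 + level / 2.0, sel.df)
    interval = (sel.estimate - tcrit * sel.se, sel.estimate + tcrit * sel.se)
    j1, j2 = sel.pair
    true_delta = scenario.means[j1 - 1] - scenario.means[j2 - 1]
    return SelectionOutcome(
        index=index, stat=sel, interval=interval, true_delta=true_delta, level=level
    )


def stats_to_frame(
    stats_list: Sequence[PairwiseStat], selected_index: int | None = None
) -> pd.DataFrame:
    """Tabular export: one row per comparison."""
    rows = []
    for i, s in enumerate(stats_list):
        rows.append(
            {
                "group1": s.pair[0],
                "group2": s.pair[1],
                "estimate": s.estimate,
                "se": s.se,
                "df": s.df,
                "t": s.t,
                "p_raw": s.p_raw,
                "p_adj": s.p_adj,
                "selected": i == selected_index,
            }
        )
    return pd.DataFrame(rows)
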