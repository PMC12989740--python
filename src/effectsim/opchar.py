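"""Monte-Carlo operating characteristics of an experimental design.

For any design specification the engine runs independent replicates and
aggregates mean squared error (MSE) of the selected effect estimate,
coverage probability (CP) of its interval, average interval length (AL),
and the rejection rate (type I error under the null, power otherwise).
Replicate-level estimates, p-values and intervals are retained by
default so estimate- and interval-distribution figures can be drawn from
the same run; a Monte-Carlo standard error accompanies the MSE because
downstream traffic-light decisions rest on it.

Reproducibility: one master seed per run; per-replicate generators are
spawned from it deterministically, so the full result is a pure function
of (spec, n_reps, master_seed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datagen import ScenarioSpec, build_scenario, spawn_rngs
from .designs import DesignSpec, run_replicate
from .multiplicity import AdjustmentContext
from .pairwise import enumerate_pairs

logger = logging.getLogger("effectsim")


@dataclass
class OperatingCharacteristics:
    """Aggregated simulation results for one design specification."""

    mse: float
    coverage: float
    avg_length: float
    rejection_rate: float
    n_reps: int
    mc_se_mse: float
    estimates: np.ndarray | None = field(default=None, repr=False)
    p_values: np.ndarray | None = field(default=None, repr=False)
    intervals: np.ndarray | None = field(default=None, repr=False)
    true_deltas: np.ndarray | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "mse": self.mse,
            "coverage": self.coverage,
            "avg_length": self.avg_length,
            "rejection_rate": self.rejection_rate,
            "n_reps": self.n_reps,
            "mc_se_mse": self.mc_se_mse,
        }


def simulate(
    spec: DesignSpec,
    n_reps: int,
    master_seed: int,
    store: bool = True,
) -> OperatingCharacteristics:
    """Run ``n_reps`` independent replicates of ``spec`` and aggregate.

    ``store=False`` drops the replicate-level vectors for memory-lean
    grid runs.  Any replicate-level failure is re-raised with the
    scenario and replicate index attached.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rngs = spawn_rngs(master_seed, n_reps)
    sq_err = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    lengths = np.empty(n_reps)
    rejected = np.empty(n_reps, dtype=bool)
    estimates = np.empty(n_reps)
    p_values = np.full(n_reps, np.nan)
    intervals = np.empty((n_reps, 2))
    true_deltas = np.empty(n_reps)
    for i, rng in enumerate(rngs):
        try:
            res = run_replicate(spec, rng)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"replicate {i} failed for design kind={spec.kind!r}, "
                f"k={spec.scenario.k}, n={spec.scenario.n_per_group}, "
                f"dmax={spec.scenario.dmax}: {exc}"
            ) from exc
        sq_err[i] = res.squared_error
        covered[i] = res.covered
        lengths[i] = res.interval_length
        rejected[i] = res.rejected
        estimates[i] = res.estimate
        if res.p_final is not None:
            p_values[i] = res.p_final
        intervals[i] = res.interval
        true_deltas[i] = res.true_delta
    mse = float(np.mean(sq_err))
    mc_se = float(np.std(sq_err, ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return OperatingCharacteristics(
        mse=mse,
        coverage=float(np.mean(covered)),
        avg_length=float(np.mean(lengths)),
        rejection_rate=float(np.mean(rejected)),
        n_reps=n_reps,
        mc_se_mse=mc_se,
        estimates=estimates if store else None,
        p_values=p_values if store else None,
        intervals=intervals if store else None,
        true_deltas=true_deltas if store else None,
    )


def make_design(
    kind: str,
    k: int,
    n: int,
    dmax: float = 0.0,
    scale: float = 1.0,
    family: str = "normal",
    effect_group: int | None = None,
    adjustment: str = "none",
    omega: float = 0.5,
    level: float = 0.95,
    alpha: float = 0.05,
    comparisons_mode: str = "all_pairwise",
    control: int | None = None,
) -> DesignSpec:
    """Convenience constructor wiring scenario, comparisons and analysis."""
    effect_group = k if effect_group is None else effect_group
    scenario = build_scenario(
        k=k, dmax=dmax, scale=scale, family=family, n=n, effect_group=effect_group
    )
    comparisons = enumerate_pairs(k, mode=comparisons_mode, control=control)
    ctx = None
    if adjustment != "none":
        ctx = AdjustmentContext(
            method=adjustment, k=k, comparison_set=comparisons, alpha=alpha
        )
    return DesignSpec(
        kind=kind,
        scenario=scenario,
        comparisons=comparisons,
        adjustment=ctx,
        omega=omega,
        level=level,
    )


def scenario_grid(
    designs: Sequence[str],
    dmax_values: Sequence[float],
    n_values: Sequence[int],
    k_values: Sequence[int],
    **kwargs,
) -> list[DesignSpec]:
    """Cartesian product of designs x effect sizes x sample sizes x groups.

    Deterministic ordering: designs vary slowest, then dmax, then n,
    then k.  Extra keyword arguments are forwarded to
    :func:`make_design`.
    """
    if not (designs and dmax_values and n_values and k_values):
        raise ValueError("all grid dimensions must be nonempty")
    specs = []
    for kind, dmax, n, k in itertools.product(designs, dmax_values, n_values, k_values):
        specs.append(make_design(kind=kind, k=k, n=n, dmax=dmax, **kwargs))
    return specs


def simulate_grid(
    specs: Sequence[DesignSpec],
    n_reps: int,
    master_seed: int,
    store: bool = False,
) -> pd.DataFrame:
    """Tidy results table: one row of operating characteristics per spec."""
    seeds = np.random.SeedSequence(master_seed).generate_state(len(specs)) % (2**31)
    rows = []
    for spec, seed in zip(specs, seeds):
        oc = simulate(spec, n_reps=n_reps, master_seed=int(seed), store=store)
        row = {
            "design": spec.kind,
            "k": spec.scenario.k,
            "n": spec.scenario.n_per_group,
            "dmax": spec.scenario.dmax,
            "family": spec.scenario.family,
            "adjustment": spec.adjustment.method if spec.adjustment else "none",
            **oc.to_row(),
        }
        rows.append(row)
        logger.info(
            "design=%s k=%d n=%d dmax=%.3g: MSE=%.4g (MC-SE %.2g) CP=%.3f AL=%.3g "
            "reject=%.3f",
            spec.kind, spec.scenario.k, spec.scenario.n_per_group,
            spec.scenario.dmax, oc.mse, oc.mc_se_mse, oc.coverage,
            oc.avg_length, oc.rejection_rate,
        )
    return pd.DataFrame(rows)
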