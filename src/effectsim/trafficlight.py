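"""Traffic-light classification of a design's null-hypothesis MSE.

A candidate design is rated against two simulated reference designs at
the same group-wise sample size:

* GREEN  — relative MSE (candidate / two-group standard design) at most
  1 plus a 5% margin: the design estimates no worse than the unbiased
  two-group comparison.
* YELLOW — relative MSE at most that of the three-group standard design
  (again with the 5% margin, applied multiplicatively): the amount of
  selection a typical reviewer would tolerate without adjustment.
* RED    — anything larger: the design requires modification.

Classification is meant for the null scenario, where selection bias is
at its worst; the same thresholds can be applied to alternative-scenario
MSEs via ``classify`` if desired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .opchar import make_design, simulate

LABELS = ("GREEN", "YELLOW", "RED")


@dataclass
class ReferencePair:
    """Null-scenario MSEs of the k=2 and k=3 standard reference designs."""

    mse_k2: float
    mse_k3: float
    mc_se_k2: float = 0.0
    mc_se_k3: float = 0.0
    n: int | None = None
    n_reps: int | None = None


@dataclass
class TrafficLightResult:
    relative_mse: float
    green_threshold: float
    yellow_threshold: float
    label: str
    margin: float
    reference_mse_k2: float
    reference_mse_k3: float


def compute_references(
    n: int,
    n_reps: int,
    seed: int,
    scale: float = 1.0,
    family: str = "normal",
) -> ReferencePair:
    """Simulate the k=2 and k=3 unadjusted standard designs under the null.

    The references are re-simulated at the candidate's group-wise n so
    the classifier is self-contained; their Monte-Carlo standard errors
    are reported because the category boundaries inherit that noise.
    """
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    oc2 = simulate(
        make_design("standard", k=2, n=n, dmax=0.0, scale=scale, family=family),
        n_reps=n_reps, master_seed=int(ss[0]), store=False,
    )
    oc3 = simulate(
        make_design("standard", k=3, n=n, dmax=0.0, scale=scale, family=family),
        n_reps=n_reps, master_seed=int(ss[1]), store=False,
    )
    return ReferencePair(
        mse_k2=oc2.mse, mse_k3=oc3.mse,
        mc_se_k2=oc2.mc_se_mse, mc_se_k3=oc3.mc_se_mse,
        n=n, n_reps=n_reps,
    )


def classify(
    candidate_mse: float,
    refs: ReferencePair,
    margin: float = 0.05,
) -> TrafficLightResult:
    """Assign GREEN / YELLOW / RED to a candidate null-hypothesis MSE.

    GREEN iff candidate/ref_k2 <= 1 + margin; YELLOW iff it is at most
    (ref_k3/ref_k2) * (1 + margin); RED otherwise.  The margin is
    multiplicative for both boundaries.
    """
    if candidate_mse <= 0 or refs.mse_k2 <= 0 or refs.mse_k3 <= 0:
        raise ValueError("MSEs must be positive")
    relative = candidate_mse / refs.mse_k2
    green_thr = 1.0 + margin
    yellow_thr = (refs.mse_k3 / refs.mse_k2) * (1.0 + margin)
    if relative <= green_thr:
        label = "GREEN"
    elif relative <= yellow_thr:
        label = "YELLOW"
    else:
        label = "RED"
    return TrafficLightResult(
        relative_mse=relative,
        green_threshold=green_thr,
        yellow_threshold=yellow_thr,
        label=label,
        margin=margin,
        reference_mse_k2=refs.mse_k2,
        reference_mse_k3=refs.mse_k3,
    )


def traffic_light_table(
    designs: Sequence[str],
    k_values: Sequence[int],
    n: int,
    n_reps: int,
    seed: int,
    margin: float = 0.05,
    omega: float = 0.5,
    dmax: float = 0.0,
) -> pd.DataFrame:
    """Label a design x k grid at fixed n (null scenario by default).

    Classification under an alternative (dmax > 0) is opt-in; the
    references remain the null-scenario two- and three-group designs.
    """
    refs = compute_references(n=n, n_reps=n_reps, seed=seed)
    child = np.random.SeedSequence(seed + 1).generate_state(
        len(designs) * len(k_values)
    ) % (2**31)
    rows = []
    i = 0
    for kind in designs:
        for k in k_values:
            spec = make_design(kind, k=k, n=n, dmax=dmax, omega=omega)
            oc = simulate(spec, n_reps=n_reps, master_seed=int(child[i]), store=False)
            res = classify(oc.mse, refs, margin=margin)
            rows.append(
                {
                    "design": kind,
                    "k": k,
                    "n": n,
                    "dmax": dmax,
                    "mse": oc.mse,
                    "mc_se_mse": oc.mc_se_mse,
                    "relative_mse": res.relative_mse,
                    "label": res.label,
                }
            )
            i += 1
    return pd.DataFrame(rows)
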