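"""Figure generation from stored replicate-level simulation results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .opchar import OperatingCharacteristics

# colorblind-safe palette for the traffic-light figure
LIGHT_COLORS = {"GREEN": "#009E73", "YELLOW": "#E69F00", "RED": "#D55E00"}


def estimate_histogram(
    oc: OperatingCharacteristics, path: str | Path, true_value: float = 0.0
) -> None:
    """Histogram of selected-effect estimates with the true value marked."""
    if oc.estimates is None:
        raise ValueError("replicate-level estimates were not stored")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(oc.estimates, bins=60, density=True, color="#56B4E9")
    ax.axvline(true_value, color="black", linestyle="--")
    ax.set_xlabel("selected effect estimate")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def interval_ribbon(
    oc: OperatingCharacteristics, path: str | Path, true_value: float = 0.0
) -> None:
    """Sorted confidence/credible intervals, non-covering ones in red."""
    if oc.intervals is None:
        raise ValueError("replicate-level intervals were not stored")
    order = np.argsort(oc.intervals[:, 0])
    ints = oc.intervals[order]
    covers = (ints[:, 0] <= true_value) & (true_value <= ints[:, 1])
    xs = np.arange(len(ints))
    fig, ax = plt.subplots(figsize=(6, 4))
    for mask, color in ((covers, "#999999"), (~covers, "#D55E00")):
        ax.vlines(xs[mask], ints[mask, 0], ints[mask, 1], color=color, lw=0.4)
    ax.axhline(true_value, color="black", linestyle="--")
    ax.set_xlabel("replicates (sorted by lower limit)")
    ax.set_ylabel("interval")
    ax.set_title(f"CP={covers.mean():.3f}, AL={np.mean(ints[:,1]-ints[:,0]):.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def traffic_light_figure(table: pd.DataFrame, path: str | Path) -> None:
    """Design x k grid of traffic-light labels as a colored matrix."""
    designs = list(dict.fromkeys(table["design"]))
    ks = sorted(table["k"].unique())
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(ks), 1.0 + 0.6 * len(designs)))
    for i, d in enumerate(designs):
        for j, k in enumerate(ks):
            sub = table[(table["design"] == d) & (table["k"] == k)]
            if sub.empty:
                continue
            label = sub["label"].iloc[0]
            ax.add_patch(
                plt.Rectangle((j, i), 1, 1, color=LIGHT_COLORS[label], ec="white")
            )
    ax.set_xlim(0, len(ks))
    ax.set_ylim(0, len(designs))
    ax.set_xticks(np.arange(len(ks)) + 0.5, ks)
    ax.set_yticks(np.arange(len(designs)) + 0.5, designs)
    ax.set_xlabel("number of groups k")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
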