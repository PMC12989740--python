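"""Synthetic data generation for multi-group experiment scenarios.

A scenario is the "true world" of a simulated experiment: ``k`` group
location parameters, a common scale, a location-scale distribution family
(normal, lognormal, or Cauchy) and a group-wise sample size.  In the
canonical scenarios used throughout the operating-characteristics
simulations, at most one group mean is nonzero and equals the maximal
mean difference ``dmax``; all other groups sit at the null.

For the lognormal family, ``location``/``scale`` parameterize the
underlying normal on the log scale (the common statistical convention);
for Cauchy they are the location and scale of the Cauchy law.  Effects
for non-normal families are therefore shifts of the *location parameter*,
which keeps the estimation target well defined even for Cauchy data,
whose mean does not exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FAMILIES = ("normal", "lognormal", "cauchy")


@dataclass(frozen=True)
class ScenarioSpec:
    """True data-generating configuration of a k-group experiment.

    Attributes
    ----------
    k : int
        Number of experimental groups (>= 2).
    means : tuple of float
        True location parameters, one per group.
    scale : float
        Common positive scale parameter.
    family : str
        One of ``normal``, ``lognormal``, ``cauchy``.
    n_per_group : int
        Group-wise sample size of the single-stage design (>= 2).
    """

    k: int
    means: tuple[float, ...]
    scale: float
    family: str = "normal"
    n_per_group: int = 6

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if len(self.means) != self.k:
            raise ValueError(
                f"means has length {len(self.means)}, expected k={self.k}"
            )
        if not np.all(np.isfinite(self.means)):
            raise ValueError("means must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.family not in FAMILIES:
            raise ValueError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))

    @property
    def dmax(self) -> float:
        """Maximal true mean difference implied by the group means."""
        return max(self.means) - min(self.means)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": list(self.means),
            "scale": self.scale,
            "family": self.family,
            "n_per_group": self.n_per_group,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        if "means" not in d:
            # (dmax, effect_group) shorthand
            return build_scenario(
                k=int(d["k"]),
                dmax=float(d.get("dmax", 0.0)),
                scale=float(d.get("scale", 1.0)),
                family=d.get("family", "normal"),
                n=int(d["n_per_group"]),
                effect_group=int(d.get("effect_group", 1)),
            )
        return cls(
            k=int(d["k"]),
            means=tuple(d["means"]),
            scale=float(d.get("scale", 1.0)),
            family=d.get("family", "normal"),
            n_per_group=int(d["n_per_group"]),
        )


@dataclass
class GroupSample:
    """Observed outcomes of one experimental group."""

    group_index: int  # 1-based
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a group sample needs at least 2 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("group sample contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


def draw_group(
    location: float,
    scale: float,
    family: str,
    n: int,
    rng: np.random.Generator,
    group_index: int = 1,
) -> GroupSample:
    """Draw ``n`` i.i.d. outcomes from the stated location-scale family.

    Parameters
    ----------
    location, scale : float
        Location and (positive) scale parameters.  For the lognormal
        family they refer to the underlying normal on the log scale.
    family : str
        ``normal``, ``lognormal`` or ``cauchy``.
    n : int
        Number of draws (>= 2).
    rng : numpy.random.Generator
        Source of randomness; identical state gives identical samples.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if family == "normal":
        values = rng.normal(loc=location, scale=scale, size=n)
    elif family == "lognormal":
        values = np.exp(rng.normal(loc=location, scale=scale, size=n))
    elif family == "cauchy":
        values = location + scale * rng.standard_cauchy(size=n)
    else:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    return GroupSample(group_index=group_index, values=values)


def draw_experiment(
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    n_per_group: int | None = None,
    groups: Sequence[int] | None = None,
) -> list[GroupSample]:
    """Draw one data set under ``scenario``.

    ``n_per_group`` overrides the scenario's sample size (used for the
    stage-wise allocations of two-stage designs); ``groups`` restricts
    drawing to a subset of 1-based group indices (stage 2 re-runs only
    the selected pair).
    """
    n = scenario.n_per_group if n_per_group is None else int(n_per_group)
    idx = range(1, scenario.k + 1) if groups is None else groups
    return [
        draw_group(
            location=scenario.means[g - 1],
            scale=scenario.scale,
            family=scenario.family,
            n=n,
            rng=rng,
            group_index=g,
        )
        for g in idx
    ]


def build_scenario(
    k: int,
    dmax: float,
    scale: float = 1.0,
    family: str = "normal",
    n: int = 6,
    effect_group: int = 1,
) -> ScenarioSpec:
    """Build the canonical one-effect scenario.

    All group means are 0 except ``means[effect_group]`` which is set to
    ``dmax`` (1-based index); ``dmax = 0`` yields the global-null
    scenario.
    """
    if not 1 <= effect_group <= k:
        raise ValueError(
            f"effect_group must be in 1..{k}, got {effect_group}"
        )
    means = [0.0] * k
    means[effect_group - 1] = float(dmax)
    return ScenarioSpec(
        k=k, means=tuple(means), scale=scale, family=family, n_per_group=n
    )


def spawn_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent, individually reproducible RNG streams.

    One master seed per simulation run; per-replicate sub-streams come
    from :class:`numpy.random.SeedSequence` spawning, so replicate ``i``
    is reproducible without re-running replicates ``0..i-1``.
    """
    ss = np.random.SeedSequence(int(master_seed))
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n)]
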