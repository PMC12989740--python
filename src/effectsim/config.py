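"""YAML run configuration: parsing, validation, round-tripping.

A run config has four blocks::

    scenario:    k, n_per_group, dmax/effect_group or explicit means,
                 family, scale
    design:      kind, comparisons (mode [+ control]), adjustment, omega,
                 level, alpha
    simulation:  n_reps, master_seed, store_replicates
    output:      directory, formats, plots

CLI flags override config keys one-for-one; the parsed object serializes
back to an identical config (round-trip invariant).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datagen import FAMILIES, ScenarioSpec
from .designs import KINDS, TWO_STAGE_KINDS, DesignSpec, allocate_stages
from .multiplicity import METHODS, AdjustmentContext
from .pairwise import MODES, enumerate_pairs


@dataclass
class RunConfig:
    scenario: dict
    design: dict
    simulation: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "scenario" not in raw or "design" not in raw:
            raise ValueError(f"{path}: config needs 'scenario' and 'design' blocks")
        return cls(
            scenario=dict(raw["scenario"]),
            design=dict(raw["design"]),
            simulation=dict(raw.get("simulation", {})),
            output=dict(raw.get("output", {})),
        )

    def to_dict(self) -> dict:
        return {
            "scenario": dict(self.scenario),
            "design": dict(self.design),
            "simulation": dict(self.simulation),
            "output": dict(self.output),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    # -- static validation ---------------------------------------------------

    def problems(self) -> list[str]:
        """Static checks only — no simulation is run."""
        out: list[str] = []
        sc, de = self.scenario, self.design
        k = sc.get("k")
        n = sc.get("n_per_group")
        if not isinstance(k, int) or k < 2:
            out.append(f"scenario.k must be an integer >= 2, got {k!r}")
        if not isinstance(n, int) or n < 2:
            out.append(f"scenario.n_per_group must be an integer >= 2, got {n!r}")
        family = sc.get("family", "normal")
        if family not in FAMILIES:
            out.append(f"scenario.family must be one of {FAMILIES}, got {family!r}")
        if sc.get("scale", 1.0) <= 0:
            out.append("scenario.scale must be positive")
        kind = de.get("kind", "standard")
        if kind not in KINDS:
            out.append(f"design.kind must be one of {KINDS}, got {kind!r}")
        mode = de.get("comparisons", "all_pairwise")
        if mode not in MODES:
            out.append(f"design.comparisons must be one of {MODES}, got {mode!r}")
        method = de.get("adjustment", "none")
        if method not in METHODS:
            out.append(f"design.adjustment must be one of {METHODS}, got {method!r}")
        if method in ("dunnett", "dunnett_stepdown") and mode != "many_to_one":
            out.append(f"adjustment {method!r} requires many_to_one comparisons")
        if method in ("tukey", "tukey_stepdown", "s2") and mode != "all_pairwise":
            out.append(f"adjustment {method!r} requires all_pairwise comparisons")
        if mode == "many_to_one" and de.get("control") is None:
            out.append("many_to_one comparisons require design.control")
        omega = de.get("omega", 0.5)
        if not 0.0 <= float(omega) <= 1.0:
            out.append(f"design.omega must be in [0, 1], got {omega!r}")
        if kind in TWO_STAGE_KINDS and isinstance(k, int) and isinstance(n, int):
            try:
                allocate_stages(k, n)
            except ValueError as exc:
                out.append(str(exc))
        n_reps = self.simulation.get("n_reps", 1000)
        if not isinstance(n_reps, int) or n_reps < 1:
            out.append(f"simulation.n_reps must be an integer >= 1, got {n_reps!r}")
        return out

    # -- construction --------------------------------------------------------

    def build_design(self) -> DesignSpec:
        problems = self.problems()
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))
        sc, de = self.scenario, self.design
        scenario = ScenarioSpec.from_dict(sc)
        mode = de.get("comparisons", "all_pairwise")
        comparisons = enumerate_pairs(
            scenario.k, mode=mode, control=de.get("control"),
            custom=de.get("custom_pairs"),
        )
        method = de.get("adjustment", "none")
        ctx = None
        if method != "none":
            ctx = AdjustmentContext(
                method=method,
                k=scenario.k,
                comparison_set=comparisons,
                alpha=float(de.get("alpha", 0.05)),
            )
        return DesignSpec(
            kind=de.get("kind", "standard"),
            scenario=scenario,
            comparisons=comparisons,
            adjustment=ctx,
            omega=float(de.get("omega", 0.5)),
            level=float(de.get("level", 0.95)),
        )
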