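"""Experiment configuration: defaults, YAML round trip, seed management.

A configuration bundles everything needed to reproduce an experiment:
network spec, payoff matrix, initialization, dynamics knobs, sweep grid
and output paths.  The defaults reproduce the headline setup — a 30x30
periodic lattice, the default payoff matrix, selection strength 0.5,
50 replicates at 20 evenly spaced sanctioner densities, and a 5,000-step
synchronous cap.  Precedence is CLI flags > config file > defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .dynamics import DynamicsConfig
from .game import PayoffMatrix
from .networks import NetworkSpec

__all__ = ["SweepSpec", "InitSection", "ExperimentConfig", "load_config", "derive_seed"]


@dataclass(frozen=True)
class SweepSpec:
    """Density grid (lo:hi inclusive, num points) and replicate count."""

    lo: float = 0.0
    hi: float = 0.95
    num: int = 20
    reps: int = 50

    def densities(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.num)


@dataclass(frozen=True)
class InitSection:
    """Initialization section: density, news ratio and placement policy.

    ``placement`` is ``random``, ``degree`` or ``betweenness``; the latter
    two target sanctioners at the top of the named centrality.
    """

    pC: float = 0.2
    ratio_a: float = 0.5
    placement: str = "random"

    def __post_init__(self):
        if self.placement not in ("random", "degree", "betweenness"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    network: NetworkSpec = field(default_factory=NetworkSpec)
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)
    init: InitSection = field(default_factory=InitSection)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    sweep: SweepSpec = field(default_factory=SweepSpec)
    seed: int = 0
    out: Optional[str] = None

    def to_dict(self) -> dict:
        def section(obj):
            return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}

        return {
            "network": section(self.network),
            "payoffs": section(self.payoffs),
            "init": section(self.init),
            "dynamics": section(self.dynamics),
            "sweep": section(self.sweep),
            "seed": self.seed,
            "out": self.out,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {"network", "payoffs", "init", "dynamics", "sweep", "seed", "out"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            network=NetworkSpec(**d.get("network", {})),
            payoffs=PayoffMatrix(**d.get("payoffs", {})),
            init=InitSection(**d.get("init", {})),
            dynamics=DynamicsConfig(**d.get("dynamics", {})),
            sweep=SweepSpec(**d.get("sweep", {})),
            seed=d.get("seed", 0),
            out=d.get("out"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def load_config(path: Optional[str]) -> ExperimentConfig:
    if path is None:
        return ExperimentConfig()
    with open(path) as fh:
        return ExperimentConfig.from_yaml(fh.read())


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and counters."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))
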