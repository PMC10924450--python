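"""Initial population construction.

A prescribed fraction ``pC`` of nodes become immutable sanctioners —
placed uniformly at random or at the top of a centrality score vector —
and every remaining node independently starts sharing the factual
narrative (A) with probability ``ratio_a``, otherwise the false one (B).
The sanctioner count is exact (``round(pC * n)``), not binomial, so that
density sweeps control the density rather than its expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import PopulationState
from .game import Strategy
from .networks import Graph

__all__ = ["InitSpec", "place_random", "place_targeted", "sanctioner_count"]


@dataclass(frozen=True)
class InitSpec:
    """How to build an initial population.

    pC : sanctioner density in [0, 1]; exactly ``round(pC * n)`` nodes.
    ratio_a : probability a viable node starts as A (0.5 by default —
        both narratives begin with equal support).
    placement : "random" or "by_score" (requires ``scores``).
    scores : per-node centrality vector for targeted placement.
    seed : seed for placement and strategy assignment.
    """

    pC: float
    ratio_a: float = 0.5
    placement: str = "random"
    scores: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pC <= 1.0:
            raise ValueError("pC must lie in [0, 1]")
        if not 0.0 <= self.ratio_a <= 1.0:
            raise ValueError("ratio_a must lie in [0, 1]")
        if self.placement not in ("random", "by_score"):
            raise ValueError(f"unknown placement {self.placement!r}")


def sanctioner_count(pC: float, n: int) -> int:
    return int(round(pC * n))


def _assign_news(strategies: np.ndarray, viable_idx: np.ndarray, ratio_a: float,
                 rng: np.random.Generator) -> None:
    draws = rng.random(len(viable_idx))
    strategies[viable_idx] = np.where(draws < ratio_a, Strategy.A, Strategy.B).astype(np.int8)


def _build_state(n: int, sanctioners: np.ndarray, ratio_a: float,
                 rng: np.random.Generator) -> PopulationState:
    strategies = np.empty(n, dtype=np.int8)
    mask = np.zeros(n, dtype=bool)
    mask[sanctioners] = True
    strategies[mask] = Strategy.C
    _assign_news(strategies, np.flatnonzero(~mask), ratio_a, rng)
    return PopulationState(strategies, mask)


def place_random(graph: Graph, spec: InitSpec, rng: np.random.Generator | None = None) -> PopulationState:
    """Uniform sanctioner placement with an exact count."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = graph.n
    n_c = sanctioner_count(spec.pC, n)
    sanctioners = rng.choice(n, size=n_c, replace=False)
    return _build_state(n, sanctioners, spec.ratio_a, rng)


def place_targeted(graph: Graph, spec: InitSpec, rng: np.random.Generator | None = None) -> PopulationState:
    """Sanctioners occupy the highest-scoring nodes.

    Ties at the admission boundary are broken by a seeded uniform draw
    (implemented as a random tie-breaking key, which also permutes nodes
    within fully admitted score classes — the selected set has the same
    law).  With constant scores this reduces exactly to random placement.
    """
    if spec.scores is None:
        raise ValueError("placement by score requires a score vector")
    scores = np.asarray(spec.scores, dtype=np.float64)
    if scores.shape != (graph.n,):
        raise ValueError("scores must have one entry per node")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_c = sanctioner_count(spec.pC, graph.n)
    tiebreak = rng.random(graph.n)
    order = np.lexsort((tiebreak, -scores))
    return _build_state(graph.n, order[:n_c], spec.ratio_a, rng)
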