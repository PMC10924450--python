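"""Replicate sweeps, critical-density estimation, and echo-chamber metrics.

The headline experiment sweeps sanctioner density and asks how often the
factual narrative ends up as the viable-population majority; the density
where that probability crosses 1/2 is the critical sanctioner density.
Echo chambers — connected same-strategy components whose interiors never
see the other narrative — are quantified by a component census, and the
pseudosteady state they produce is detected from the per-step activity
series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.sparse.csgraph import connected_components as _cc

from .dynamics import DynamicsConfig, PopulationState, RunResult, run
from .game import DEFAULT_PAYOFFS, PayoffMatrix, Strategy
from .networks import Graph
from .seeding import InitSpec, place_random, place_targeted

__all__ = [
    "SweepResult",
    "CriticalDensityEstimate",
    "NoCrossingError",
    "EchoChamberCensus",
    "StrategyComponent",
    "dominance_sweep",
    "estimate_critical_density",
    "echo_chamber_census",
    "detect_pseudosteady",
    "pseudosteady_onset",
    "persistence_probe",
]


class NoCrossingError(ValueError):
    """The dominance curve never crosses 1/2 on the swept range."""


@dataclass
class SweepResult:
    """Dominance-probability estimates on a sanctioner-density grid.

    ``p_dominant_a[i]`` estimates the probability that the factual
    narrative holds the viable majority at density ``densities[i]``; ties
    (equal A and B counts, the signature of a fragmented viable layer)
    count 1/2.
    """

    densities: np.ndarray
    p_dominant_a: np.ndarray
    reps: int
    n_a_dominant: np.ndarray
    n_b_dominant: np.ndarray
    n_tie: np.ndarray
    master_seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density": self.densities,
                "reps": self.reps,
                "n_A_dominant": self.n_a_dominant,
                "n_B_dominant": self.n_b_dominant,
                "n_tie": self.n_tie,
                "p_dominant_A": self.p_dominant_a,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CriticalDensityEstimate:
    """Density where the monotone-smoothed dominance curve crosses 1/2."""

    pc_star: float
    method: str
    bracket: tuple[float, float]


def dominance_sweep(
    network_factory: Graph | Callable[[int], Graph],
    densities: Sequence[float],
    reps: int,
    dynamics_config: DynamicsConfig = DynamicsConfig(),
    master_seed: int = 0,
    *,
    ratio_a: float = 0.5,
    placement: str = "random",
    scores_fn: Callable[[Graph], np.ndarray] | None = None,
    M: PayoffMatrix = DEFAULT_PAYOFFS,
) -> SweepResult:
    """Tally viable-majority outcomes over a density grid.

    ``network_factory`` is either a fixed :class:`Graph` (deterministic
    substrates such as the lattice) or a callable ``seed -> Graph``, in
    which case a fresh network is generated for every replicate (random
    ensembles such as small worlds).  Replicate streams are derived from
    ``master_seed`` by the counter scheme ``SeedSequence([master_seed,
    density_index, rep])``, so any cell can be reproduced in isolation.

    For ``placement="by_score"`` the per-network score vector comes from
    ``scores_fn`` (e.g. :func:`~misinfogame.networks.degree_scores`).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    densities = np.asarray(list(densities), dtype=np.float64)
    if ((densities < 0) | (densities > 1)).any():
        raise ValueError("densities must lie in [0, 1]")
    if placement == "by_score" and scores_fn is None:
        raise ValueError('placement="by_score" requires scores_fn')
    fixed_graph = network_factory if isinstance(network_factory, Graph) else None
    fixed_scores = None
    if fixed_graph is not None and placement == "by_score":
        fixed_scores = scores_fn(fixed_graph)

    n_a_dom = np.zeros(len(densities), dtype=np.int64)
    n_b_dom = np.zeros(len(densities), dtype=np.int64)
    n_tie = np.zeros(len(densities), dtype=np.int64)
    for di, pc in enumerate(densities):
        for r in range(reps):
            ss = np.random.SeedSequence([int(master_seed), di, r])
            net_seed, init_seed, run_seed = (int(x) for x in ss.generate_state(3) % (2**31))
            if fixed_graph is not None:
                graph, scores = fixed_graph, fixed_scores
            else:
                graph = network_factory(net_seed)
                scores = scores_fn(graph) if placement == "by_score" else None
            spec = InitSpec(pC=float(pc), ratio_a=ratio_a,
                            placement="by_score" if placement == "by_score" else "random",
                            scores=scores, seed=init_seed)
            init_rng = np.random.default_rng(init_seed)
            if placement == "by_score":
                state = place_targeted(graph, spec, init_rng)
            else:
                state = place_random(graph, spec, init_rng)
            result = run(state, graph, M, replace(dynamics_config, seed=run_seed))
            if result.dominant == "A":
                n_a_dom[di] += 1
            elif result.dominant == "B":
                n_b_dom[di] += 1
            else:
                n_tie[di] += 1
    p_dom = (n_a_dom + 0.5 * n_tie) / reps
    return SweepResult(densities, p_dom, reps, n_a_dom, n_b_dom, n_tie, int(master_seed))


def estimate_critical_density(sweep: SweepResult) -> CriticalDensityEstimate:
    """Interpolate where the dominance curve crosses 1/2.

    The raw curve is non-monotone at very high densities (the fragmented
    regime hovers at 1/2), so the fit is restricted to densities up to the
    curve's argmax, monotone-smoothed there by isotonic regression, and
    linearly interpolated at 1/2.
    """
    d = sweep.densities
    y = sweep.p_dominant_a
    if len(d) < 2:
        raise NoCrossingError("need at least two grid densities")
    turnover = int(np.argmax(y))
    d_fit, y_fit = d[: turnover + 1], y[: turnover + 1]
    smooth = isotonic_regression(y_fit).x
    above = smooth >= 0.5
    if not above.any() or above[0]:
        lo, hi = float(d[0]), float(d[-1])
        raise NoCrossingError(
            f"dominance curve does not cross 0.5 inside the swept range [{lo}, {hi}]"
        )
    j = int(np.argmax(above))  # first index at or above 1/2
    if smooth[j] == 0.5:
        return CriticalDensityEstimate(float(d_fit[j]), "isotonic+linear", (float(d_fit[j]), float(d_fit[j])))
    i = j - 1
    frac = (0.5 - smooth[i]) / (smooth[j] - smooth[i])
    pc_star = float(d_fit[i] + frac * (d_fit[j] - d_fit[i]))
    return CriticalDensityEstimate(pc_star, "isotonic+linear", (float(d_fit[i]), float(d_fit[j])))


@dataclass
class StrategyComponent:
    """One connected same-strategy component of the viable subgraph.

    A member is *interior* when every viable neighbor shares its strategy
    (a node with no viable neighbors is vacuously interior); otherwise it
    sits on the component boundary, exposed to the other narrative.
    """

    strategy: Strategy
    members: np.ndarray
    interior: int
    boundary: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EchoChamberCensus:
    components_a: list[StrategyComponent]
    components_b: list[StrategyComponent]

    def components(self, strategy: Strategy) -> list[StrategyComponent]:
        return self.components_a if strategy == Strategy.A else self.components_b

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": comp.strategy.name,
                "size": comp.size,
                "interior": comp.interior,
                "boundary": comp.boundary,
                "smallest_member": int(comp.members[0]),
            }
            for comp in self.components_a + self.components_b
        ]
        return pd.DataFrame(rows, columns=["strategy", "size", "interior", "boundary", "smallest_member"])


def echo_chamber_census(state: PopulationState, graph: Graph) -> EchoChamberCensus:
    """Component census of each news strategy on the viable subgraph."""
    adj = graph.to_sparse()
    viable = state.viable
    s = state.strategies
    out: dict[Strategy, list[StrategyComponent]] = {}
    for strat in (Strategy.A, Strategy.B):
        nodes = np.flatnonzero(viable & (s == strat))
        comps: list[StrategyComponent] = []
        if len(nodes):
            sub = adj[nodes][:, nodes]
            ncomp, labels = _cc(sub, directed=False)
            # interior: all *viable* neighbors share the strategy
            same = adj[:, nodes].sum(axis=1).A1 if hasattr(adj[:, nodes].sum(axis=1), "A1") else np.asarray(adj[:, nodes].sum(axis=1)).ravel()
            viable_deg = np.asarray(adj[:, np.flatnonzero(viable)].sum(axis=1)).ravel()
            interior_mask = same[nodes] == viable_deg[nodes]
            for cid in range(ncomp):
                members = nodes[labels == cid]
                ni = int(interior_mask[labels == cid].sum())
                comps.append(StrategyComponent(strat, members, ni, len(members) - ni))
            comps.sort(key=lambda comp: (-comp.size, int(comp.members[0])))
        out[strat] = comps
    return EchoChamberCensus(out[Strategy.A], out[Strategy.B])


def detect_pseudosteady(activity: np.ndarray, threshold: float = 0.01, window: int = 10) -> Optional[int]:
    """First step from which activity stays below ``threshold`` for ``window`` steps.

    Returns None when no such step exists within the series.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if window < 1:
        raise ValueError("window must be >= 1")
    activity = np.asarray(activity, dtype=np.float64)
    below = activity < threshold
    if len(below) < window:
        return None
    ok = np.lib.stride_tricks.sliding_window_view(below, window).all(axis=1)
    hits = np.flatnonzero(ok)
    return int(hits[0]) if len(hits) else None


def pseudosteady_onset(result: RunResult, threshold: float = 0.01, window: int = 10) -> Optional[int]:
    """Pseudosteady detection on a finished run.

    A run that reached fixation stays unchanged forever, so its activity
    series is padded with zeros to let the window extend past the end.
    """
    activity = result.activity
    if result.outcome in ("A_fixed", "B_fixed"):
        activity = np.concatenate([activity, np.zeros(window)])
    return detect_pseudosteady(activity, threshold, window)


def persistence_probe(
    state: PopulationState,
    graph: Graph,
    M: PayoffMatrix,
    config: DynamicsConfig,
    horizon: int,
) -> float:
    """Jaccard similarity of the fake-news-sharer set across ``horizon`` steps.

    Continues the dynamics from ``state`` and compares the B-node set
    before and after; two empty sets count as identical (similarity 1).
    """
    before = set(np.flatnonzero(state.strategies == Strategy.B).tolist())
    cont = run(state, graph, M, replace(config, max_steps=horizon))
    after = set(np.flatnonzero(cont.final_state.strategies == Strategy.B).tolist())
    union = before | after
    if not union:
        return 1.0
    return len(before & after) / len(union)
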