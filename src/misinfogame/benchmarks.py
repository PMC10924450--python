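"""Headline reproduction protocols at desk scale.

Each function runs one of the package's reference experiments from
scratch — the critical sanctioner densities on the lattice and on
small-world ensembles, the small-world shortcut count, the echo-chamber
formation speed, and the weak-selection single-mutant crossing — at
problem sizes a single CPU handles in minutes.  Replicate counts and
grids are the package's reference choices; all randomness derives from
the ``master_seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .analytics import WeakSelectionParams, weak_selection_terms
from .dynamics import DynamicsConfig, fixation_frequency, run
from .experiments import dominance_sweep, estimate_critical_density, pseudosteady_onset
from .game import DEFAULT_PAYOFFS, PayoffMatrix
from .networks import make_lattice, make_small_world
from .seeding import InitSpec, place_random

__all__ = [
    "critical_density_lattice",
    "critical_density_small_world",
    "mean_shortcut_count",
    "echo_chamber_onset_median",
    "single_mutant_crossing",
]

_SWEEP_CONFIG = DynamicsConfig(beta=0.5, update="synchronous", payoff_mode="sum", max_steps=5000)


def critical_density_lattice(
    master_seed: int,
    reps: int = 24,
    densities=None,
) -> float:
    """Critical sanctioner density on the 30x30 periodic lattice.

    Synchronous death–birth updates at beta = 0.5 to fixation or 5,000
    steps; the density grid brackets the reference tipping point.
    """
    if densities is None:
        densities = np.round(np.arange(0.16, 0.325, 0.02), 3)
    graph = make_lattice(30, 30)
    sweep = dominance_sweep(graph, densities, reps, _SWEEP_CONFIG, master_seed=master_seed)
    return estimate_critical_density(sweep).pc_star


def critical_density_small_world(
    master_seed: int,
    reps: int = 24,
    densities=None,
) -> float:
    """Critical density on WS(900, 8, 0.03), fresh network per replicate."""
    if densities is None:
        densities = np.round(np.arange(0.10, 0.305, 0.025), 3)

    def factory(seed: int):
        return make_small_world(900, 8, 0.03, seed=seed).graph

    sweep = dominance_sweep(factory, densities, reps, _SWEEP_CONFIG, master_seed=master_seed)
    return estimate_critical_density(sweep).pc_star


def mean_shortcut_count(master_seed: int, n_seeds: int = 200) -> float:
    """Mean rewired-edge count of WS(900, 8, 0.03) under the per-stub convention."""
    rng = np.random.SeedSequence(master_seed)
    seeds = rng.generate_state(n_seeds) % (2**31)
    return float(np.mean([make_small_world(900, 8, 0.03, seed=int(s)).n_rewired for s in seeds]))


def echo_chamber_onset_median(
    master_seed: int,
    reps: int = 20,
    pC: float = 0.15,
    threshold: float = 0.01,
    window: int = 10,
) -> float:
    """Median synchronous step count until the pseudosteady criterion holds.

    Pseudosteady: per-step strategy-change fraction below ``threshold`` of
    viable nodes for ``window`` consecutive steps.  Runs that never meet
    the criterion count at the step cap.
    """
    graph = make_lattice(30, 30)
    onsets = []
    for r in range(reps):
        ss = np.random.SeedSequence([int(master_seed), r])
        init_seed, run_seed = (int(x) for x in ss.generate_state(2) % (2**31))
        init = place_random(graph, InitSpec(pC=pC, seed=init_seed))
        result = run(init, graph, DEFAULT_PAYOFFS,
                     DynamicsConfig(beta=0.5, max_steps=5000, payoff_mode="sum", seed=run_seed))
        onset = pseudosteady_onset(result, threshold=threshold, window=window)
        onsets.append(onset if onset is not None else result.config.max_steps)
    return float(np.median(onsets))


def single_mutant_crossing(
    master_seed: int,
    rows: int = 8,
    cols: int = 8,
    pC: float = 0.2,
    beta: float = 0.005,
    reps: int = 40000,
    gamma_offset: float = 3.0,
) -> dict:
    """Simulated vs predicted crossing of the single-mutant benchmark line.

    On a small periodic lattice the closed forms predict the punishment
    level ``gamma*`` at which a lone truth-sharer's fixation probability
    equals the neutral benchmark 1/N.  Monte-Carlo fixation frequencies
    are measured at ``gamma* -/+ gamma_offset`` and the empirical crossing
    interpolated between them.  ``beta`` sits at the upper edge of the
    weak-selection regime so the O(beta) signal is resolvable at modest
    replicate counts; the predicted crossing location is exactly
    beta-independent because the correction is linear in beta.
    """
    graph = make_lattice(rows, cols)
    n = graph.n
    n_c = round(pC * n)
    N = n - n_c
    pc_eff = n_c / n

    def coefficient(gamma: float) -> float:
        t = weak_selection_terms(WeakSelectionParams(
            M=PayoffMatrix(gamma=gamma), k=4, N=N, pC=pc_eff, beta=beta, p=1 / N))
        return -t.u1 - 3 * t.u2

    # the coefficient is linear in gamma: root from two evaluations
    c0, c1 = coefficient(0.0), coefficient(-1.0)
    gamma_star = c0 / (c1 - c0)

    points = {}
    for i, gamma in enumerate((gamma_star - gamma_offset, gamma_star + gamma_offset)):
        out = fixation_frequency(
            graph, PayoffMatrix(gamma=float(gamma)), beta=beta,
            n_sanctioners=n_c, n_a=1, reps=reps,
            seed=int(np.random.SeedSequence([int(master_seed), i]).generate_state(1)[0] % 2**31),
            payoff_mode="sum", max_draws=15 * N * n)
        points[float(gamma)] = {"rho_hat": out["fix_a"],
                                "se": float(np.sqrt(out["fix_a"] * (1 - out["fix_a"]) / reps)),
                                "stalled": out["stalled"]}
    gammas = sorted(points)
    r_lo, r_hi = points[gammas[0]]["rho_hat"], points[gammas[1]]["rho_hat"]
    benchmark = 1.0 / N
    if r_lo != r_hi:
        gamma_hat = gammas[0] + (benchmark - r_lo) * (gammas[1] - gammas[0]) / (r_hi - r_lo)
    else:
        gamma_hat = np.nan
    return {
        "gamma_star_predicted": float(gamma_star),
        "gamma_hat_empirical": float(gamma_hat),
        "benchmark": benchmark,
        "N": N,
        "points": points,
    }
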