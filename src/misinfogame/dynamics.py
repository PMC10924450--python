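"""Death–birth imitation dynamics with immutable sanctioners.

A focal node replaces its strategy by copying one of its neighbors, drawn
with probability proportional to fitness ``exp(beta * pi)``.  Sanctioners
(strategy C) never update and are never copied: they contribute to their
neighbors' payoffs (that is how they punish) but are excluded from every
imitation lottery.  A viable node whose neighbors are all sanctioners is
frozen at its initial strategy.

Two update schedules are provided.  The synchronous step recomputes all
payoffs once and lets every viable node imitate simultaneously against
that frozen profile (double-buffered, no within-step feedback).  The
asynchronous step draws a single node uniformly from *all* nodes — a draw
that lands on a sanctioner is a no-op but still advances the clock — so
``n`` asynchronous steps correspond to roughly one synchronous step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game import DEFAULT_PAYOFFS, PayoffMatrix, PayoffProfile, Strategy, _padded_neighbors, payoff_profile
from .networks import Graph

__all__ = [
    "PopulationState",
    "DynamicsConfig",
    "RunResult",
    "imitation_draw",
    "step_synchronous",
    "step_asynchronous",
    "run",
    "exact_fixation_oracle",
    "fixation_frequency",
]


@dataclass
class PopulationState:
    """Per-node strategies plus the immutable sanctioner mask.

    The mask and the set of C strategies coincide at every step; only
    unmasked (viable) nodes ever change strategy, so the number and
    placement of sanctioners is constant along any trajectory.
    """

    strategies: np.ndarray  # int8, values in {0=A, 1=B, 2=C}
    sanctioner_mask: np.ndarray  # bool
    t: int = 0

    def __post_init__(self):
        self.strategies = np.asarray(self.strategies, dtype=np.int8)
        self.sanctioner_mask = np.asarray(self.sanctioner_mask, dtype=bool)
        if self.strategies.shape != self.sanctioner_mask.shape:
            raise ValueError("strategies and sanctioner_mask must have equal length")
        if not ((self.strategies == Strategy.C) == self.sanctioner_mask).all():
            raise ValueError("sanctioner_mask must coincide with C strategies")

    @property
    def n(self) -> int:
        return len(self.strategies)

    @property
    def viable(self) -> np.ndarray:
        return ~self.sanctioner_mask

    def counts(self) -> tuple[int, int, int]:
        """(#A, #B, #C)."""
        c = np.bincount(self.strategies, minlength=3)
        return int(c[0]), int(c[1]), int(c[2])

    def copy(self) -> "PopulationState":
        return PopulationState(self.strategies.copy(), self.sanctioner_mask.copy(), self.t)


@dataclass(frozen=True)
class DynamicsConfig:
    """Knobs of the update process.

    beta : selection strength (>= 0); 0.5 is the headline value.
    update : "synchronous" or "asynchronous".
    payoff_mode : "sum" (accumulated payoff over all neighbors, default)
        or "mean" (expected payoff against a random neighbor); on
        k-regular graphs the two differ only by rescaling beta by k.  The
        accumulated convention is the calibration that reproduces the
        reference critical sanctioner densities at beta = 0.5.
    max_steps : trajectory cap; 5,000 synchronous steps by default.
    seed : master seed for the run.
    """

    beta: float = 0.5
    update: str = "synchronous"
    payoff_mode: str = "sum"
    max_steps: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.update not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown update rule {self.update!r}")
        if self.payoff_mode not in ("mean", "sum"):
            raise ValueError(f"unknown payoff mode {self.payoff_mode!r}")


@dataclass
class RunResult:
    """Outcome of one trajectory.

    ``outcome`` is ``A_fixed``/``B_fixed`` when the other news strategy
    went extinct among viable nodes, ``timeout`` at the step cap (or for a
    population with no viable A/B contest to run).  ``dominant`` is the
    strict majority among viable nodes, ``tie`` on equality.  ``activity``
    records, per step, the fraction of viable nodes that changed strategy.
    """

    outcome: str
    dominant: str
    steps_run: int
    final_state: PopulationState
    activity: np.ndarray
    config: DynamicsConfig
    seed: int

    def to_record(self, include_strategies: bool = False) -> dict:
        nA, nB, nC = self.final_state.counts()
        record = {
            "outcome": self.outcome,
            "dominant": self.dominant,
            "steps_run": self.steps_run,
            "update": self.config.update,
            "beta": self.config.beta,
            "payoff_mode": self.config.payoff_mode,
            "max_steps": self.config.max_steps,
            "seed": self.seed,
            "counts": {"A": nA, "B": nB, "C": nC},
        }
        if include_strategies:
            record["strategies"] = self.final_state.strategies.tolist()
        return record


def imitation_draw(
    node: int,
    state: PopulationState,
    graph: Graph,
    profile: PayoffProfile,
    rng: np.random.Generator,
) -> Strategy:
    """Strategy the focal node would adopt this update.

    One non-C neighbor is drawn with probability proportional to its
    fitness; with no non-C neighbor the node keeps its current strategy.
    The focal node's own fitness plays no role.
    """
    nbrs = graph.neighbors(node)
    s = state.strategies
    w = np.where(s[nbrs] != Strategy.C, profile.f[nbrs], 0.0)
    total = w.sum()
    if total <= 0.0:
        return Strategy(int(s[node]))
    u = rng.random() * total
    j = nbrs[int(np.searchsorted(np.cumsum(w), u, side="right"))]
    return Strategy(int(s[j]))


def _sync_update(strategies, viable, nbr, deg, arr4, beta, mean_mode, rng):
    """One vectorized synchronous sweep; returns the new strategy array."""
    n, K = nbr.shape
    s_ext = np.append(strategies, np.int8(3))
    s_nb = s_ext[nbr]
    pay = arr4[strategies[:, None].astype(np.int64), s_nb.astype(np.int64)]
    pi = pay.sum(axis=1)
    if mean_mode:
        pi = np.where(deg > 0, pi / np.maximum(deg, 1), 0.0)
    e = beta * pi
    mx = e.max() if n else 0.0
    if mx > 500.0:
        e = e - (mx - 500.0)
    f = np.exp(e)
    w_ext = np.append(np.where(viable, f, 0.0), 0.0)
    W = w_ext[nbr]
    cum = np.cumsum(W, axis=1)
    tot = cum[:, -1]
    u = rng.random(n) * tot
    idx = np.minimum((cum <= u[:, None]).sum(axis=1), K - 1)
    chosen = s_ext[nbr[np.arange(n), idx]]
    updatable = viable & (tot > 0.0)
    return np.where(updatable, chosen, strategies).astype(np.int8)


def step_synchronous(
    state: PopulationState,
    graph: Graph,
    M: PayoffMatrix,
    config: DynamicsConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Simultaneous imitation by every viable node against frozen payoffs."""
    nbr, deg = _padded_neighbors(graph)
    arr4 = np.zeros((3, 4))
    arr4[:, :3] = M.as_array()
    new = _sync_update(
        state.strategies, state.viable, nbr, deg, arr4, config.beta,
        config.payoff_mode == "mean", rng,
    )
    return PopulationState(new, state.sanctioner_mask.copy(), state.t + 1)


def step_asynchronous(
    state: PopulationState,
    graph: Graph,
    M: PayoffMatrix,
    config: DynamicsConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Single uniformly drawn node updates; sanctioner draws are no-ops."""
    new = state.copy()
    new.t = state.t + 1
    node = int(rng.integers(state.n))
    if state.sanctioner_mask[node]:
        return new
    profile = payoff_profile(state, graph, M, config.beta, config.payoff_mode)
    new.strategies[node] = imitation_draw(node, state, graph, profile, rng)
    return new


def run(
    initial: PopulationState,
    graph: Graph,
    M: PayoffMatrix = DEFAULT_PAYOFFS,
    config: DynamicsConfig = DynamicsConfig(),
) -> RunResult:
    """Iterate the configured update until fixation or the step cap.

    Fully reproducible from ``(config.seed, config, initial)``.  The
    activity series holds one entry per executed step.
    """
    rng = np.random.default_rng(config.seed)
    s = initial.strategies.copy()
    viable = initial.viable
    n = initial.n
    n_viable = int(viable.sum())
    counts = np.bincount(s[viable], minlength=3) if n_viable else np.zeros(3, int)
    nA, nB = int(counts[0]), int(counts[1])
    activity: list[float] = []

    def finish(steps: int) -> RunResult:
        final = PopulationState(s, initial.sanctioner_mask.copy(), initial.t + steps)
        if n_viable and nB == 0 and nA > 0:
            outcome = "A_fixed"
        elif n_viable and nA == 0 and nB > 0:
            outcome = "B_fixed"
        else:
            outcome = "timeout"
        dominant = "A" if nA > nB else ("B" if nB > nA else "tie")
        return RunResult(outcome, dominant, steps, final,
                         np.asarray(activity, dtype=np.float64), config, config.seed)

    if n_viable == 0 or nA == 0 or nB == 0:
        return finish(0)

    sync = config.update == "synchronous"
    nbr, deg = _padded_neighbors(graph)
    arr4 = np.zeros((3, 4))
    arr4[:, :3] = M.as_array()
    mean_mode = config.payoff_mode == "mean"
    s_work = s
    for step in range(config.max_steps):
        if sync:
            new = _sync_update(s_work, viable, nbr, deg, arr4, config.beta, mean_mode, rng)
            changed = int((new != s_work).sum())
            s_work = new
            c = np.bincount(s_work[viable], minlength=3)
            nA, nB = int(c[0]), int(c[1])
        else:
            node = int(rng.integers(n))
            changed = 0
            if viable[node]:
                nbrs = graph.neighbors(node)
                if len(nbrs):
                    s_ext = np.append(s_work, np.int8(3))
                    rows = nbr[nbrs]
                    pay = arr4[s_work[nbrs][:, None].astype(np.int64), s_ext[rows].astype(np.int64)]
                    pi = pay.sum(axis=1)
                    if mean_mode:
                        pi = pi / np.maximum(deg[nbrs], 1)
                    e = config.beta * pi
                    mx = e.max()
                    if mx > 500.0:
                        e = e - (mx - 500.0)
                    w = np.where(s_work[nbrs] != 2, np.exp(e), 0.0)
                    tot = w.sum()
                    if tot > 0.0:
                        u = rng.random() * tot
                        j = nbrs[int(np.searchsorted(np.cumsum(w), u, side="right"))]
                        old, new_s = int(s_work[node]), int(s_work[j])
                        if old != new_s:
                            s_work[node] = new_s
                            changed = 1
                            if new_s == 0:
                                nA += 1
                                nB -= 1
                            else:
                                nA -= 1
                                nB += 1
        activity.append(changed / n_viable)
        if nA == 0 or nB == 0:
            s = s_work
            return finish(step + 1)
    s = s_work
    return finish(config.max_steps)


def exact_fixation_oracle(
    graph: Graph,
    M: PayoffMatrix,
    config: DynamicsConfig,
    initial: PopulationState,
    max_viable: int = 12,
) -> float:
    """Exact P(all viable nodes end up A) for the asynchronous chain.

    Enumerates every A/B labeling of the viable nodes (state space
    ``2^V``), builds the single-step transition matrix of the asynchronous
    update, and solves the absorbing-chain linear system.  Closed states
    other than all-A (including frozen mixed configurations created by
    sanctioner walls) contribute 0.  Refuses above ``max_viable`` viable
    nodes.
    """
    viable_nodes = np.flatnonzero(initial.viable)
    V = len(viable_nodes)
    if V > max_viable:
        raise ValueError(f"{V} viable nodes exceeds the oracle limit {max_viable}")
    if V == 0:
        return 0.0
    n = graph.n
    pos = {int(v): i for i, v in enumerate(viable_nodes)}
    arr = M.as_array()
    nstates = 1 << V
    all_a = nstates - 1  # bit set = node plays A

    def strategies_of(mask: int) -> np.ndarray:
        s = np.full(n, 2, dtype=np.int64)
        for v, i in pos.items():
            s[v] = 0 if (mask >> i) & 1 else 1
        return s

    # transition matrix over labelings (dense; V <= 12 -> at most 4096^2)
    T = np.zeros((nstates, nstates))
    for mask in range(nstates):
        s = strategies_of(mask)
        stay = (n - V) / n  # sanctioner draws are no-ops
        for v, i in pos.items():
            nbrs = graph.neighbors(v)
            w_a = w_b = 0.0
            for j in nbrs:
                if s[j] == 2:
                    continue
                pj = arr[s[j], s[graph.neighbors(j)]].sum()
                if config.payoff_mode == "mean":
                    pj /= len(graph.neighbors(j))
                w = np.exp(config.beta * pj)
                if s[j] == 0:
                    w_a += w
                else:
                    w_b += w
            tot = w_a + w_b
            if tot <= 0.0:
                stay += 1 / n  # frozen node: its draw changes nothing
                continue
            p_a, p_b = w_a / tot, w_b / tot
            m_a = mask | (1 << i)
            m_b = mask & ~(1 << i)
            T[mask, m_a] += p_a / n
            T[mask, m_b] += p_b / n
        T[mask, mask] += stay
    closed = np.isclose(np.diag(T), 1.0)
    rho = np.zeros(nstates)
    rho[all_a] = 1.0
    transient = ~closed
    idx = np.flatnonzero(transient)
    if len(idx):
        Q = T[np.ix_(idx, idx)]
        # rho_t = Q rho_t + (one-step flow into closed states, weighted by their rho)
        b = T[np.ix_(idx, np.flatnonzero(closed))] @ rho[closed]
        rho[idx] = np.linalg.solve(np.eye(len(idx)) - Q, b)
    init_mask = 0
    for v, i in pos.items():
        if initial.strategies[v] == 0:
            init_mask |= 1 << i
    return float(rho[init_mask])


# ---------------------------------------------------------------------------
# Batched Monte-Carlo fixation frequencies (numba-accelerated)

_FIX_KERNEL = None


def _get_fix_kernel():
    global _FIX_KERNEL
    if _FIX_KERNEL is None:
        import numba

        @numba.njit(cache=False)
        def kernel(indptr, indices, arr, beta, mean_mode, n_sanc, n_a, reps, max_draws, seed):
            np.random.seed(seed)
            n = len(indptr) - 1
            fix_a = 0
            fix_b = 0
            stalled = 0
            perm = np.empty(n, dtype=np.int64)
            s = np.empty(n, dtype=np.int8)
            for _ in range(reps):
                # sanctioners then A players drawn without replacement
                for i in range(n):
                    perm[i] = i
                for i in range(n_sanc + n_a):
                    j = i + np.random.randint(n - i)
                    perm[i], perm[j] = perm[j], perm[i]
                for i in range(n):
                    s[i] = 1
                for i in range(n_sanc):
                    s[perm[i]] = 2
                for i in range(n_sanc, n_sanc + n_a):
                    s[perm[i]] = 0
                nA = n_a
                nB = n - n_sanc - n_a
                if nA == 0 or nB == 0:
                    if nB == 0 and nA > 0:
                        fix_a += 1
                    elif nA == 0 and nB > 0:
                        fix_b += 1
                    continue
                done = False
                for _ in range(max_draws):
                    node = np.random.randint(n)
                    if s[node] == 2:
                        continue
                    w_a = 0.0
                    w_b = 0.0
                    for jj in range(indptr[node], indptr[node + 1]):
                        j = indices[jj]
                        if s[j] == 2:
                            continue
                        pj = 0.0
                        degj = indptr[j + 1] - indptr[j]
                        for ll in range(indptr[j], indptr[j + 1]):
                            pj += arr[s[j], s[indices[ll]]]
                        if mean_mode:
                            pj /= degj
                        w = np.exp(beta * pj)
                        if s[j] == 0:
                            w_a += w
                        else:
                            w_b += w
                    tot = w_a + w_b
                    if tot <= 0.0:
                        continue
                    u = np.random.random() * tot
                    new_s = 0 if u < w_a else 1
                    if new_s != s[node]:
                        if new_s == 0:
                            nA += 1
                            nB -= 1
                        else:
                            nA -= 1
                            nB += 1
                        s[node] = new_s
                        if nA == 0:
                            fix_b += 1
                            done = True
                            break
                        if nB == 0:
                            fix_a += 1
                            done = True
                            break
                if not done:
                    stalled += 1
            return fix_a, fix_b, stalled

        _FIX_KERNEL = kernel
    return _FIX_KERNEL


def fixation_frequency(
    graph: Graph,
    M: PayoffMatrix,
    *,
    beta: float,
    n_sanctioners: int,
    n_a: int,
    reps: int,
    seed: int,
    payoff_mode: str = "mean",
    max_draws: int | None = None,
) -> dict:
    """Monte-Carlo fixation frequencies under asynchronous updating.

    Each replicate places ``n_sanctioners`` sanctioners and ``n_a`` initial
    A players uniformly at random (exact counts) and runs the asynchronous
    death–birth chain until one news strategy goes extinct among viable
    nodes or ``max_draws`` single-node updates elapse.  Replicates still
    mixed at the cap — possible when sanctioner walls freeze components —
    are reported as ``stalled``.  Used to validate the weak-selection
    closed forms; numba-compiled for throughput.
    """
    n = graph.n
    if max_draws is None:
        n_viable = n - n_sanctioners
        max_draws = max(200 * n * max(n_viable, 1), 10_000)
    kernel = _get_fix_kernel()
    arr = M.as_array()
    fix_a, fix_b, stalled = kernel(
        graph.indptr.astype(np.int64),
        graph.indices.astype(np.int64),
        arr,
        float(beta),
        payoff_mode == "mean",
        int(n_sanctioners),
        int(n_a),
        int(reps),
        int(max_draws),
        int(seed) % (2**31),
    )
    return {
        "fix_a": fix_a / reps,
        "fix_b": fix_b / reps,
        "stalled": stalled / reps,
        "reps": reps,
    }
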