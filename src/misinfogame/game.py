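"""The three-strategy news-sharing game.

Two narratives compete on a social network: a factual one (strategy A) and
a false one (strategy B).  A third, immutable type C — the sanctioner —
behaves like a truth-sharer toward A players but inflicts a punishment
payoff ``gamma`` on adjacent fake-news sharers.  Sharing is a coordination
game: matching the partner pays, and B–B coordination pays more than A–A,
encoding the empirical advantage viral falsehoods enjoy.  Since sanctioners
never update strategy, their own payoff row is irrelevant and fixed at
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Strategy",
    "PayoffMatrix",
    "DEFAULT_PAYOFFS",
    "PayoffProfile",
    "pair_payoff",
    "expected_payoff",
    "fitness",
    "payoff_profile",
]

# exponent cap used when converting payoffs to imitation weights; shifting
# all exponents by a common constant leaves every lottery unchanged
_EXP_CAP = 500.0


class Strategy(IntEnum):
    A = 0  # shares the factual narrative
    B = 1  # shares the false narrative
    C = 2  # sanctioner: immutable, punishes B neighbors


@dataclass(frozen=True)
class PayoffMatrix:
    """Row-player payoffs of the 3x3 game.

    ``entry(s1, s2)`` is the payoff to the ``s1`` player when interacting
    with an ``s2`` neighbor.  The C row is identically zero by convention.

    Parameters
    ----------
    a, b, alpha : payoffs to an A player against A, B, C neighbors.
    c, d, gamma : payoffs to a B player against A, B, C neighbors;
        ``gamma`` is the sanctioning punishment, typically negative.
    """

    a: float = 1.0
    b: float = 0.0
    alpha: float = 1.0
    c: float = 0.0
    d: float = 2.0
    gamma: float = -4.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.a, self.b, self.alpha],
                [self.c, self.d, self.gamma],
                [0.0, 0.0, 0.0],
            ]
        )

    def entry(self, s1: int, s2: int) -> float:
        return float(self.as_array()[int(s1), int(s2)])


#: Default instantiation: A–A coordination 1, B–B coordination 2,
#: sanction punishment −4, and sanctioners treated as truth-sharers by A.
DEFAULT_PAYOFFS = PayoffMatrix()


@dataclass(frozen=True)
class PayoffProfile:
    """Per-node expected payoff pi and fitness exp(beta * pi).

    ``shift`` records the common constant subtracted from ``beta * pi``
    before exponentiating when needed to avoid overflow; imitation
    lotteries are invariant to it.
    """

    pi: np.ndarray
    f: np.ndarray
    shift: float = 0.0


def pair_payoff(s1: Strategy | int, s2: Strategy | int, M: PayoffMatrix = DEFAULT_PAYOFFS) -> float:
    """Payoff to the row player ``s1`` from a single interaction with ``s2``."""
    return M.entry(s1, s2)


def expected_payoff(node, state, graph, M: PayoffMatrix = DEFAULT_PAYOFFS, mode: str = "mean") -> float:
    """Expected payoff of one node against its current neighborhood.

    ``mean`` (default) averages the pairwise payoff over all neighbors —
    sanctioner neighbors included as opponents; ``sum`` returns the
    unaveraged total.  An isolated node earns 0 in either mode.
    """
    nbrs = graph.neighbors(node)
    if len(nbrs) == 0:
        return 0.0
    arr = M.as_array()
    s = state.strategies
    total = float(arr[s[node], s[nbrs]].sum())
    if mode == "sum":
        return total
    if mode == "mean":
        return total / len(nbrs)
    raise ValueError(f"unknown payoff mode {mode!r}")


def fitness(pi, beta: float):
    """Exponential payoff-to-fitness map ``exp(beta * pi)``.

    ``beta`` is the selection strength; at ``beta = 0`` every node has
    fitness 1 and the dynamics reduce to neutral drift.
    """
    if beta < 0:
        raise ValueError("selection strength beta must be >= 0")
    return np.exp(beta * np.asarray(pi, dtype=np.float64)) if np.ndim(pi) else float(np.exp(beta * pi))


def payoff_profile(state, graph, M: PayoffMatrix, beta: float, mode: str = "mean") -> PayoffProfile:
    """Vectorized payoffs and fitnesses for the whole population.

    The fitness exponents are shifted by a common constant only when they
    would overflow; the shift is reported in the profile and cancels in
    every imitation lottery.
    """
    if beta < 0:
        raise ValueError("selection strength beta must be >= 0")
    arr4 = np.zeros((3, 4))
    arr4[:, :3] = M.as_array()
    s = state.strategies
    s_ext = np.append(s, 3).astype(np.int64)
    nbr, deg = _padded_neighbors(graph)
    pay = arr4[s[:, None], s_ext[nbr]]
    pi = pay.sum(axis=1)
    if mode == "mean":
        pi = np.where(deg > 0, pi / np.maximum(deg, 1), 0.0)
    elif mode != "sum":
        raise ValueError(f"unknown payoff mode {mode!r}")
    e = beta * pi
    shift = float(max(0.0, e.max() - _EXP_CAP)) if len(e) else 0.0
    return PayoffProfile(pi=pi, f=np.exp(e - shift), shift=shift)


def _padded_neighbors(graph) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor lists padded to a rectangular table.

    Returns ``(nbr, deg)`` where ``nbr`` is ``(n, K)`` with the sentinel
    value ``n`` in unused cells (callers index strategy arrays extended by
    one sentinel slot).
    """
    deg = graph.degrees
    n = graph.n
    K = int(deg.max()) if n else 0
    nbr = np.full((n, max(K, 1)), n, dtype=np.int64)
    if K:
        cols = np.arange(K)
        mask = cols[None, :] < deg[:, None]
        nbr[:, :K][mask] = graph.indices
    return nbr, deg
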