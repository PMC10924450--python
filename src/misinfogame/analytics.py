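"""Closed-form layer: well-mixed threshold and weak-selection fixation.

Two analytic companions to the simulator.  First, an infinite well-mixed
population under replicator dynamics: with sanctioner density ``pC`` and
the remaining population split evenly between the two narratives, the
factual strategy is favored exactly when its initial expected payoff
exceeds the false one's, which yields a closed-form critical density
(1/11 for the default payoffs).  Second, a pair-approximation result for
k-regular graphs in the weak-selection limit: the fixation probabilities
of the two news strategies are linear corrections to neutral drift,

    rho_A(p) ~ p + (beta * N * p * (1 - p) / (6 k)) * (-u1 - 3 u2),
    rho_B(p) ~ p + (beta * N * p * (1 - p) / (6 k)) * (-w1 - 3 w2),

with ``w1 = u1`` and ``w2 = -(u1 + u2)``, where ``N`` is the *viable*
population size.  A strategy is favored by selection when its single-
mutant fixation probability exceeds the neutral benchmark ``1/N``.

Transcription note
------------------
The inner factor of ``u1`` is corrupted in our source for these closed
forms (superscripts and fraction bars are lost in the text, leaving the
ambiguous token ``(1-k2-1+k(pC-1))``).  ``weak_selection_terms`` therefore
exposes the candidate readings and defaults to the one that survives the
numerical validations: agreement with Monte-Carlo fixation frequencies of
the simulator at small beta, and the qualitative structure of the
``pC``–``gamma`` phase diagram (strong punishment needs about a fifth of
the population sanctioning; vanishing punishment about half).  See
``docs/methods.md`` for the validation evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .game import DEFAULT_PAYOFFS, PayoffMatrix

__all__ = [
    "WellMixedResult",
    "WeakSelectionParams",
    "WeakSelectionTerms",
    "FixationResult",
    "U1_INNER_READINGS",
    "DEFAULT_U1_READING",
    "replicator_initial_payoffs",
    "well_mixed_dominance",
    "well_mixed_threshold",
    "weak_selection_terms",
    "rho",
    "phase_classify",
    "minimal_pc_for_A",
]


@dataclass(frozen=True)
class WellMixedResult:
    """Initial expected payoffs and the replicator threshold density.

    ``pc_star`` is exact (rational arithmetic when the payoffs are
    rational).  When the unclipped threshold falls outside [0, 1] the
    reported value is clipped and ``always_favored`` names the strategy
    favored at every interior density.
    """

    fA0: Fraction
    fB0: Fraction
    pc_star: Optional[Fraction] = None
    always_favored: Optional[str] = None


@dataclass(frozen=True)
class WeakSelectionParams:
    """Inputs of the weak-selection closed forms.

    k : common degree of the regular network (>= 2).
    N : viable population size (sanctioners excluded).
    pC : sanctioner density.
    beta : selection strength; the expansion is first-order in beta and
        trusted only for beta << 1 (a warning is suggested above 0.01).
    p : initial fraction of the focal news strategy among viable nodes.
    """

    M: PayoffMatrix = DEFAULT_PAYOFFS
    k: int = 4
    N: int = 720
    pC: float = 0.2
    beta: float = 1e-4
    p: float = 0.5

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if not 0.0 <= self.pC <= 1.0:
            raise ValueError("pC must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class WeakSelectionTerms:
    """Coefficient combinations entering the fixation closed forms."""

    u1: float
    u2: float
    w1: float
    w2: float


@dataclass(frozen=True)
class FixationResult:
    rhoA: float
    rhoB: float
    favored_A: bool
    favored_B: bool


def _as_fraction(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x)


def replicator_initial_payoffs(M: PayoffMatrix, pC) -> tuple[Fraction, Fraction]:
    """Initial expected payoffs of the two narratives in a well-mixed population.

    With sanctioner density ``pC`` and ``pA = pB = (1 - pC) / 2``:
    ``fA0 = a pA + b pB + alpha pC`` and ``fB0 = c pA + d pB + gamma pC``.
    """
    pC = _as_fraction(pC)
    if not 0 <= pC <= 1:
        raise ValueError("pC must lie in [0, 1]")
    half = (1 - pC) / 2
    a, b, al = _as_fraction(M.a), _as_fraction(M.b), _as_fraction(M.alpha)
    c, d, ga = _as_fraction(M.c), _as_fraction(M.d), _as_fraction(M.gamma)
    fA0 = a * half + b * half + al * pC
    fB0 = c * half + d * half + ga * pC
    return fA0, fB0


def well_mixed_dominance(M: PayoffMatrix, pC) -> float:
    """Replicator prediction for P(factual narrative dominates): 0, 1/2 or 1.

    In the coordination game the initially fitter narrative only gains
    ground, so the outcome is a step function of the payoff comparison.
    """
    fA0, fB0 = replicator_initial_payoffs(M, pC)
    if fA0 > fB0:
        return 1.0
    if fA0 < fB0:
        return 0.0
    return 0.5


def well_mixed_threshold(M: PayoffMatrix = DEFAULT_PAYOFFS) -> WellMixedResult:
    """Critical sanctioner density of the well-mixed replicator model.

    Solving ``fA0 = fB0`` gives
    ``pc* = (c + d - a - b) / ((c + d - a - b) + 2 (alpha - gamma))``,
    computed in exact rational arithmetic.  A degenerate denominator means
    the two payoffs never cross; a threshold outside [0, 1] is clipped and
    flagged with the strategy favored at every interior density.
    """
    a, b, al = _as_fraction(M.a), _as_fraction(M.b), _as_fraction(M.alpha)
    c, d, ga = _as_fraction(M.c), _as_fraction(M.d), _as_fraction(M.gamma)
    num = c + d - a - b
    den = num + 2 * (al - ga)
    if den == 0:
        raise ZeroDivisionError(
            "degenerate payoff combination: initial payoffs never cross"
        )
    pc_star = num / den
    fA_half, fB_half = replicator_initial_payoffs(M, Fraction(1, 2))
    if pc_star < 0 or pc_star > 1:
        favored = "A" if fA_half > fB_half else "B"
        clipped = Fraction(0) if pc_star < 0 else Fraction(1)
        fA0, fB0 = replicator_initial_payoffs(M, clipped)
        return WellMixedResult(fA0, fB0, clipped, favored)
    fA0, fB0 = replicator_initial_payoffs(M, pc_star)
    always = None
    if pc_star == 0:
        always = "A"  # boundary case: A favored at every interior density
    elif pc_star == 1:
        always = "B"
    return WellMixedResult(fA0, fB0, pc_star, always)


# Candidate readings of the corrupted u1 inner factor, as functions of
# (k, pC).  Keys spell out the reconstructed expression.
U1_INNER_READINGS: dict[str, Callable[[float, float], float]] = {
    # 1 - k^2 - 1 + k (pC - 1)  (flat superscript reading)
    "-k^2+k(pC-1)": lambda k, pC: -(k**2) + k * (pC - 1),
    # 1 - 2k - 1 + k (pC - 1)  ("k2" as k * 2)
    "-2k+k(pC-1)": lambda k, pC: -2 * k + k * (pC - 1),
    # (1 - k) 2 - 1 + k (pC - 1)
    "2(1-k)-1+k(pC-1)": lambda k, pC: 2 * (1 - k) - 1 + k * (pC - 1),
    # (1 - k^2) / (-1 + k (pC - 1))  (lost fraction bar)
    "(1-k^2)/(-1+k(pC-1))": lambda k, pC: (1 - k**2) / (-1 + k * (pC - 1)),
    # (1 - k)/2 - 1 + k (pC - 1)  (lost fraction bar, k/2 reading)
    "(1-k)/2-1+k(pC-1)": lambda k, pC: (1 - k) / 2 - 1 + k * (pC - 1),
}

#: Reading selected by the numerical validations (see module docstring).
DEFAULT_U1_READING = "-2k+k(pC-1)"


def weak_selection_terms(
    params: WeakSelectionParams,
    reading: str = None,
) -> WeakSelectionTerms:
    """The u/w coefficient combinations of the fixation closed forms.

    ``u1 = (a - b - c + d) * inner(k, pC) * (1 - pC)`` with the inner
    factor given by the selected transcription ``reading`` (see
    ``U1_INNER_READINGS`` and the module docstring);
    ``u2 = -a + b + c - d - a k + b k - b k^2 + d k^2
    + (k - 1) (c + (b - alpha + gamma) k - d (1 + k)) pC``.
    The identities ``w1 = u1`` and ``w2 = -(u1 + u2)`` hold by
    construction.
    """
    if reading is None:
        reading = DEFAULT_U1_READING
    inner = U1_INNER_READINGS[reading]
    M, k, pC = params.M, params.k, params.pC
    a, b, al, c, d, ga = M.a, M.b, M.alpha, M.c, M.d, M.gamma
    u1 = (a - b - c + d) * inner(k, pC) * (1 - pC)
    u2 = (
        -a + b + c - d
        - a * k + b * k - b * k**2 + d * k**2
        + (k - 1) * (c + (b - al + ga) * k - d * (1 + k)) * pC
    )
    return WeakSelectionTerms(u1=u1, u2=u2, w1=u1, w2=-(u1 + u2))


def rho(params: WeakSelectionParams, reading: str = None) -> FixationResult:
    """Weak-selection fixation probabilities and favored flags.

    ``rhoA``/``rhoB`` evaluate the closed forms at ``params.p``; the
    favored flags compare the single-mutant value (p = 1/N) against the
    neutral benchmark 1/N.  At beta = 0 both reduce exactly to neutral
    drift, rho(p) = p.
    """
    import warnings

    if params.beta > 0.01:
        warnings.warn(
            f"beta={params.beta} is outside the weak-selection regime (<= 0.01); "
            "the first-order expansion may be inaccurate",
            stacklevel=2,
        )
    terms = weak_selection_terms(params, reading)
    pref = params.beta * params.N / (6 * params.k)
    p = params.p

    def _curve(c1: float, c2: float, x: float) -> float:
        return x + pref * x * (1 - x) * (-c1 - 3 * c2)

    p1 = 1.0 / params.N
    return FixationResult(
        rhoA=_curve(terms.u1, terms.u2, p),
        rhoB=_curve(terms.w1, terms.w2, p),
        favored_A=_curve(terms.u1, terms.u2, p1) > p1,
        favored_B=_curve(terms.w1, terms.w2, p1) > p1,
    )


def phase_classify(
    M_base: PayoffMatrix = DEFAULT_PAYOFFS,
    k: int = 4,
    N: int = 720,
    beta: float = 1e-4,
    pC_grid=None,
    gamma_grid=None,
    reading: str = None,
) -> pd.DataFrame:
    """Label the pC–gamma plane by which narrative selection favors.

    For every grid point the punishment entry of the base matrix is
    replaced by ``gamma`` and the single-mutant favored flags computed;
    labels are ``A_favored``, ``B_favored``, ``neither`` or ``both``.
    Long-format frame with columns (pC, gamma, label).
    """
    if pC_grid is None:
        pC_grid = np.linspace(0.0, 1.0, 101)
    if gamma_grid is None:
        gamma_grid = np.linspace(0.0, -8.0, 81)
    rows = []
    for pc in np.asarray(pC_grid, dtype=float):
        for ga in np.asarray(gamma_grid, dtype=float):
            M = PayoffMatrix(M_base.a, M_base.b, M_base.alpha, M_base.c, M_base.d, float(ga))
            res = rho(WeakSelectionParams(M=M, k=k, N=N, pC=float(pc), beta=beta, p=1.0 / N),
                      reading)
            if res.favored_A and res.favored_B:
                label = "both"
            elif res.favored_A:
                label = "A_favored"
            elif res.favored_B:
                label = "B_favored"
            else:
                label = "neither"
            rows.append({"pC": float(pc), "gamma": float(ga), "label": label})
    return pd.DataFrame(rows)


def minimal_pc_for_A(
    gamma: float,
    M_base: PayoffMatrix = DEFAULT_PAYOFFS,
    k: int = 4,
    N: int = 720,
    beta: float = 1e-4,
    grid: np.ndarray | None = None,
    reading: str = None,
) -> Optional[float]:
    """Smallest sanctioner density at which selection favors the factual news."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 1001)
    M = PayoffMatrix(M_base.a, M_base.b, M_base.alpha, M_base.c, M_base.d, float(gamma))
    for pc in grid:
        res = rho(WeakSelectionParams(M=M, k=k, N=N, pC=float(pc), beta=beta, p=1.0 / N), reading)
        if res.favored_A:
            return float(pc)
    return None
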