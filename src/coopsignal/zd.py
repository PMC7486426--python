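"""Zero-determinant (ZD) memory-one strategy algebra.

A memory-one strategy is a vector of four cooperation probabilities
p = (p_CC, p_CD, p_DC, p_DD), conditioned on the previous round's outcome
from the strategist's own perspective, plus a first-round move.  Press and
Dyson showed that strategies whose shifted vector

    p~ = (p_CC - 1, p_CD - 1, p_DC, p_DD)

lies in the span of the two players' payoff vectors and the ones vector,

    p~ = alpha * S_X + beta * S_Y + gamma * 1,
    S_X = (R, S, T, P),  S_Y = (R, T, S, P),

unilaterally enforce the linear relation alpha*s_X + beta*s_Y + gamma = 0
between the long-run per-round payoffs s_X (strategist) and s_Y (co-player).
We report the relation as s_X - ell = chi * (s_Y - ell) with baseline
ell = -gamma/(alpha+beta) and slope chi = -beta/alpha.  Extortion pins the
baseline at P (the strategist's surplus over mutual defection is chi times
the co-player's); generosity pins it at R (the strategist absorbs a
chi-fold share of any shortfall below mutual cooperation).

The two strategies used in the behavioral study are provided as module
constants with exact rational entries: printed percentages 69.2 / 53.8 and
18.2 / 36.4 are 9/13, 7/13, 2/11 and 4/11.

This module works in exact :class:`fractions.Fraction` arithmetic whenever
the inputs are rational, so certificates of the study strategies are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Sequence

import numpy as np

from .game import (
    OUTCOME_INDEX,
    Move,
    Outcome,
    PayoffMatrix,
    outcome_of,
)

__all__ = [
    "MemoryOneStrategy",
    "ZDParams",
    "ZDCertificate",
    "OutcomeDistribution",
    "PayoffPair",
    "InfeasibleParametersError",
    "make_zd",
    "zd_certificate",
    "zd_complete",
    "stationary_distribution",
    "expected_payoffs",
    "EXTORTION",
    "GENEROSITY",
    "ALWAYS_COOPERATE",
    "ALWAYS_DEFECT",
    "TIT_FOR_TAT",
]


class InfeasibleParametersError(ValueError):
    """ZD parameters that put a cooperation probability outside [0, 1]."""


def _snap(x, tol: float = 5e-4):
    """Snap a decimal probability to a small-denominator rational.

    Printed probabilities such as 0.692 are rounded versions of exact
    rationals (9/13); snapping makes downstream payoff identities exact.
    Values further than ``tol`` from every fraction with denominator <= 13
    are returned unchanged.
    """
    if isinstance(x, Rational):
        return Fraction(x)
    f = Fraction(float(x)).limit_denominator(13)
    if abs(float(f) - float(x)) <= tol:
        return f
    return float(x)


@dataclass(frozen=True)
class MemoryOneStrategy:
    """Memory-one policy: cooperation probabilities by previous outcome.

    Attributes
    ----------
    p : tuple
        (p_CC, p_CD, p_DC, p_DD), each in [0, 1]; entries may be exact
        :class:`~fractions.Fraction` values.
    initial : Move
        First-round move.
    name : str
        Optional label used in logs and config files.
    """

    p: tuple
    initial: Move = Move.C
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.p) != 4:
            raise ValueError("p must have exactly 4 entries (CC, CD, DC, DD)")
        for label, v in zip(("p_CC", "p_CD", "p_DC", "p_DD"), self.p):
            if not (0 <= float(v) <= 1):
                raise ValueError(f"{label}={v} outside [0, 1]")
        object.__setattr__(self, "p", tuple(self.p))
        object.__setattr__(self, "initial", Move(self.initial))

    @classmethod
    def from_decimals(
        cls, p: Sequence[float], initial: Move = Move.C, name: str = "", snap: bool = True
    ) -> "MemoryOneStrategy":
        """Build a strategy from decimal probabilities.

        With ``snap=True`` (the default for study-style inputs), entries
        within 5e-4 of a fraction with denominator <= 13 are stored as that
        exact rational.
        """
        entries = tuple(_snap(x) if snap else float(x) for x in p)
        return cls(entries, initial, name)

    def prob(self, prev: Outcome):
        """Cooperation probability after a previous outcome."""
        return self.p[OUTCOME_INDEX[Outcome(prev)]]

    def initial_cooperation_prob(self) -> float:
        return 1.0 if self.initial is Move.C else 0.0

    def shifted(self) -> tuple:
        """Press-Dyson shifted vector p~ = (p1-1, p2-1, p3, p4)."""

        def sub1(x):
            return x - (Fraction(1) if isinstance(x, Rational) else 1.0)

        return (sub1(self.p[0]), sub1(self.p[1]), self.p[2], self.p[3])


#: Extortion strategy of the study: baseline P, slope 3; starts with defection.
EXTORTION = MemoryOneStrategy(
    (Fraction(9, 13), Fraction(0), Fraction(7, 13), Fraction(0)),
    initial=Move.D,
    name="extortion",
)

#: Generous strategy of the study: baseline R, slope 3; starts with cooperation.
GENEROSITY = MemoryOneStrategy(
    (Fraction(1), Fraction(2, 11), Fraction(1), Fraction(4, 11)),
    initial=Move.C,
    name="generosity",
)

ALWAYS_COOPERATE = MemoryOneStrategy((1, 1, 1, 1), Move.C, "always-cooperate")
ALWAYS_DEFECT = MemoryOneStrategy((0, 0, 0, 0), Move.D, "always-defect")
TIT_FOR_TAT = MemoryOneStrategy((1, 0, 1, 0), Move.C, "tit-for-tat")


@dataclass(frozen=True)
class ZDParams:
    """Parameters of the ZD construction.

    ell is the baseline payoff of the enforced relation (P for extortion,
    R for generosity), chi >= 1 its slope, and phi > 0 a free scale that
    must keep all four probabilities inside [0, 1].
    """

    ell: Fraction
    chi: Fraction
    phi: Fraction

    def __post_init__(self) -> None:
        if float(self.phi) <= 0:
            raise ValueError("phi must be > 0")
        if float(self.chi) < 1:
            raise ValueError("chi must be >= 1")


@dataclass(frozen=True)
class ZDCertificate:
    """Result of fitting p~ = alpha*S_X + beta*S_Y + gamma*1.

    ``residual`` is the max absolute misfit of the least-squares solution;
    a strategy is certified ZD when it does not exceed ``tol``.  ``baseline``
    (-gamma/(alpha+beta)) and ``slope`` (-beta/alpha) are None when their
    denominators vanish (e.g. tit-for-tat has alpha + beta = 0: it enforces
    s_X = s_Y at every baseline).
    """

    alpha: float
    beta: float
    gamma: float
    residual: float
    baseline: float | None
    slope: float | None
    is_zd: bool
    tol: float

    def as_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "beta": float(self.beta),
            "gamma": float(self.gamma),
            "residual": float(self.residual),
            "baseline": None if self.baseline is None else float(self.baseline),
            "slope": None if self.slope is None else float(self.slope),
            "is_zd": bool(self.is_zd),
            "tol": float(self.tol),
        }


def _all_rational(*vals) -> bool:
    return all(isinstance(v, Rational) for v in vals)


def make_zd(params: ZDParams, m: PayoffMatrix | None = None) -> MemoryOneStrategy:
    """Construct the ZD strategy with baseline ell, slope chi and scale phi.

    The construction sets p~_i = phi * [(S_X,i - ell) - chi * (S_Y,i - ell)]
    and shifts back to probabilities.  Raises
    :class:`InfeasibleParametersError` naming the first entry that falls
    outside [0, 1].  The first-round move follows the study convention:
    defect for the extortion baseline (ell = P), cooperate for baselines
    above P.
    """
    m = m or PayoffMatrix.study()
    exact = _all_rational(params.ell, params.chi, params.phi, m.T, m.R, m.P, m.S)
    conv = Fraction if exact else float
    ell, chi, phi = conv(params.ell), conv(params.chi), conv(params.phi)
    sx = [conv(v) for v in m.focal_vector()]
    sy = [conv(v) for v in m.other_vector()]
    one = conv(1)
    shift = (one, one, conv(0), conv(0))
    p = []
    for i, label in enumerate(("p_CC", "p_CD", "p_DC", "p_DD")):
        val = phi * ((sx[i] - ell) - chi * (sy[i] - ell)) + shift[i]
        if not (0 <= float(val) <= 1):
            raise InfeasibleParametersError(
                f"{label} = {float(val):.6g} outside [0, 1] for "
                f"ell={float(ell)}, chi={float(chi)}, phi={float(phi)}"
            )
        p.append(val)
    initial = Move.D if float(ell) <= float(m.P) else Move.C
    return MemoryOneStrategy(tuple(p), initial=initial, name=f"zd(ell={float(ell)}, chi={float(chi)})")


def zd_certificate(
    p: MemoryOneStrategy, m: PayoffMatrix | None = None, tol: float = 1e-6
) -> ZDCertificate:
    """Fit the ZD linear system by least squares and certify the strategy.

    Solves the 4-equation, 3-unknown system p~ = alpha*S_X + beta*S_Y +
    gamma*1 in the least-squares sense; the residual is the max absolute
    misfit.  Non-ZD strategies are a result (is_zd=False), never an error.
    """
    m = m or PayoffMatrix.study()
    pt = np.array([float(v) for v in p.shifted()])
    A = np.column_stack(
        [
            np.array(m.focal_vector(), dtype=float),
            np.array(m.other_vector(), dtype=float),
            np.ones(4),
        ]
    )
    coef, *_ = np.linalg.lstsq(A, pt, rcond=None)
    alpha, beta, gamma = coef
    residual = float(np.max(np.abs(A @ coef - pt)))
    denom_b = alpha + beta
    baseline = float(-gamma / denom_b) if abs(denom_b) > 1e-12 else None
    slope = float(-beta / alpha) if abs(alpha) > 1e-12 else None
    return ZDCertificate(
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        residual=residual,
        baseline=baseline,
        slope=slope,
        is_zd=residual <= tol,
        tol=tol,
    )


def zd_complete(
    p_partial: Sequence, m: PayoffMatrix | None = None, initial: Move | None = None
) -> MemoryOneStrategy:
    """Pin the single unknown entry of a strategy by requiring it to be ZD.

    ``p_partial`` is a length-4 sequence with exactly one entry ``None``.
    The unknown entry and (alpha, beta, gamma) jointly solve the 4x4 linear
    system p~ = alpha*S_X + beta*S_Y + gamma*1.  Raises ``ValueError`` if
    the system is singular (no unique completion) and
    :class:`InfeasibleParametersError` if the solution leaves [0, 1].
    """
    m = m or PayoffMatrix.study()
    entries = list(p_partial)
    unknown = [i for i, v in enumerate(entries) if v is None]
    if len(unknown) != 1:
        raise ValueError("exactly one entry must be None")
    k = unknown[0]
    sx = np.array(m.focal_vector(), dtype=float)
    sy = np.array(m.other_vector(), dtype=float)
    shift = np.array([1.0, 1.0, 0.0, 0.0])
    # Unknowns x = (alpha, beta, gamma, p_k); equations
    #   alpha*S_X,i + beta*S_Y,i + gamma - [i == k]*p_k = p~_i
    # with p~_k's known part = -shift_k on the right-hand side.
    A = np.column_stack([sx, sy, np.ones(4), np.zeros(4)])
    A[k, 3] = -1.0
    b = np.empty(4)
    for i in range(4):
        b[i] = -shift[i] if i == k else float(entries[i]) - shift[i]
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("singular system: no unique ZD completion")
    x = np.linalg.solve(A, b)
    pk = float(x[3])
    if not (-1e-12 <= pk <= 1 + 1e-12):
        labels = ("p_CC", "p_CD", "p_DC", "p_DD")
        raise InfeasibleParametersError(
            f"ZD completion {labels[k]} = {pk:.6g} outside [0, 1]"
        )
    entries[k] = min(1.0, max(0.0, pk))
    if initial is None:
        cert_baseline = zd_certificate(
            MemoryOneStrategy(tuple(entries), Move.C), m
        ).baseline
        initial = (
            Move.D
            if cert_baseline is not None and cert_baseline <= float(m.P) + 1e-9
            else Move.C
        )
    return MemoryOneStrategy(tuple(entries), initial=initial, name="zd-completed")


@dataclass(frozen=True)
class OutcomeDistribution:
    """Long-run frequencies of (CC, CD, DC, DD)."""

    pi: np.ndarray
    method: str  # "stationary" or "cesaro"

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi < -1e-9) or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("outcome distribution must be a length-4 simplex vector")
        object.__setattr__(self, "pi", np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum())

    def __getitem__(self, outcome: Outcome) -> float:
        return float(self.pi[OUTCOME_INDEX[Outcome(outcome)]])


@dataclass(frozen=True)
class PayoffPair:
    """Long-run per-round payoffs of the two players."""

    s_X: float
    s_Y: float


def transition_matrix(p: MemoryOneStrategy, q: MemoryOneStrategy) -> np.ndarray:
    """4x4 outcome transition matrix (rows: current outcome, focal view)."""
    flip = (0, 2, 1, 3)
    M = np.empty((4, 4))
    for i in range(4):
        a = float(p.p[i])
        b = float(q.p[flip[i]])
        M[i] = (a * b, a * (1 - b), (1 - a) * b, (1 - a) * (1 - b))
    return M


def stationary_distribution(p: MemoryOneStrategy, q: MemoryOneStrategy) -> OutcomeDistribution:
    """Long-run outcome distribution of the match p vs q.

    When the outcome chain has a unique stationary vector it is returned
    (solved from the balance equations).  Degenerate chains — reducible or
    periodic, which arise from deterministic entries — fall back to the
    Cesaro (long-run average) distribution started from the two initial
    moves; the certificate of the computation is the ``method`` field.
    """
    M = transition_matrix(p, q)
    A = M.T - np.eye(4)
    # Unique stationary vector iff rank(M^T - I) == 3.
    if np.linalg.matrix_rank(A, tol=1e-10) == 3:
        G = np.vstack([A, np.ones(4)])
        rhs = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        pi, *_ = np.linalg.lstsq(G, rhs, rcond=None)
        if np.all(pi > -1e-9):
            return OutcomeDistribution(pi, "stationary")
    # Cesaro average by doubling: C_{2n} = (C_n + M^n C_n)/2.
    start = outcome_of(p.initial, q.initial)
    v0 = np.zeros(4)
    v0[OUTCOME_INDEX[start]] = 1.0
    C = np.eye(4)
    Pn = M.copy()
    for _ in range(60):
        C = 0.5 * (C + Pn @ C)
        Pn = Pn @ Pn
    pi = v0 @ C
    return OutcomeDistribution(pi, "cesaro")


def expected_payoffs(
    p: MemoryOneStrategy, q: MemoryOneStrategy, m: PayoffMatrix | None = None
) -> PayoffPair:
    """Long-run per-round payoffs (s_X, s_Y) = (pi . S_X, pi . S_Y)."""
    m = m or PayoffMatrix.study()
    pi = stationary_distribution(p, q).pi
    s_x = float(pi @ np.array(m.focal_vector(), dtype=float))
    s_y = float(pi @ np.array(m.other_vector(), dtype=float))
    return PayoffPair(s_X=s_x, s_Y=s_y)
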