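"""Stage game and iterated-match engine for the prisoner's dilemma.

The stage game is the standard two-player prisoner's dilemma with payoffs
T > R > P > S: mutual cooperation pays R to each, mutual defection P,
and unilateral defection pays T to the defector and S to the cooperator.
Matches iterate the stage game for a fixed number of rounds between two
policies; memory-one policies condition on the previous round's outcome.

Outcome 4-vectors are always indexed (CC, CD, DC, DD), first letter the
focal player's move, second the co-player's. This ordering is shared by
every module that touches an outcome-indexed quantity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Move",
    "Outcome",
    "OUTCOMES",
    "PayoffMatrix",
    "MatchRecord",
    "outcome_of",
    "flip_outcome",
    "payoffs_of",
    "play_match",
    "simulate_outcome_counts",
]


class Move(str, enum.Enum):
    """A single-round action: cooperate or defect."""

    C = "C"
    D = "D"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Outcome(str, enum.Enum):
    """A round outcome from the focal player's perspective."""

    CC = "CC"
    CD = "CD"
    DC = "DC"
    DD = "DD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical outcome ordering used for every outcome-indexed 4-vector.
OUTCOMES: tuple[Outcome, ...] = (Outcome.CC, Outcome.CD, Outcome.DC, Outcome.DD)

#: Index of each outcome in :data:`OUTCOMES`.
OUTCOME_INDEX: dict[Outcome, int] = {o: i for i, o in enumerate(OUTCOMES)}

_FLIP = {
    Outcome.CC: Outcome.CC,
    Outcome.CD: Outcome.DC,
    Outcome.DC: Outcome.CD,
    Outcome.DD: Outcome.DD,
}


def outcome_of(focal: Move, other: Move) -> Outcome:
    """Encode a pair of moves as an outcome, focal move first."""
    return Outcome(Move(focal).value + Move(other).value)


def flip_outcome(outcome: Outcome) -> Outcome:
    """Re-encode an outcome from the co-player's perspective (CD <-> DC)."""
    return _FLIP[Outcome(outcome)]


@dataclass(frozen=True)
class PayoffMatrix:
    """Stage-game payoffs with the prisoner's-dilemma ordering T > R > P > S.

    Attributes
    ----------
    T : float
        Temptation payoff (defect against a cooperator).
    R : float
        Reward for mutual cooperation.
    P : float
        Punishment for mutual defection.
    S : float
        Sucker payoff (cooperate against a defector).
    """

    T: float = 7
    R: float = 5
    P: float = 3
    S: float = 2

    def __post_init__(self) -> None:
        vals = (self.T, self.R, self.P, self.S)
        if not all(np.isfinite(float(v)) for v in vals):
            raise ValueError("payoffs must be finite")
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P > S, got T={self.T}, "
                f"R={self.R}, P={self.P}, S={self.S}"
            )

    @classmethod
    def study(cls) -> "PayoffMatrix":
        """The matrix used in the behavioral study: T=7, R=5, P=3, S=2."""
        return cls(T=7, R=5, P=3, S=2)

    def focal_vector(self) -> tuple:
        """Focal-player payoffs over (CC, CD, DC, DD): (R, S, T, P)."""
        return (self.R, self.S, self.T, self.P)

    def other_vector(self) -> tuple:
        """Co-player payoffs over (CC, CD, DC, DD): (R, T, S, P)."""
        return (self.R, self.T, self.S, self.P)


def payoffs_of(outcome: Outcome, m: PayoffMatrix) -> tuple[float, float]:
    """Per-round points for (focal, other) under a given outcome."""
    i = OUTCOME_INDEX[Outcome(outcome)]
    return (m.focal_vector()[i], m.other_vector()[i])


@dataclass(frozen=True)
class RoundResult:
    round: int
    focal_move: Move
    other_move: Move
    outcome: Outcome
    focal_points: float
    other_points: float


@dataclass
class MatchRecord:
    """Round-by-round log of a single iterated match."""

    rounds: list[RoundResult] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def focal_total(self) -> float:
        return sum(r.focal_points for r in self.rounds)

    @property
    def other_total(self) -> float:
        return sum(r.other_points for r in self.rounds)

    def outcome_counts(self) -> np.ndarray:
        """Counts of (CC, CD, DC, DD) across rounds."""
        counts = np.zeros(4, dtype=np.int64)
        for r in self.rounds:
            counts[OUTCOME_INDEX[r.outcome]] += 1
        return counts

    def focal_cooperation_rate(self) -> float:
        return sum(r.focal_move is Move.C for r in self.rounds) / self.n_rounds

    def to_frame(self) -> pd.DataFrame:
        """Round log as a DataFrame (CSV-serializable)."""
        return pd.DataFrame(
            {
                "round": [r.round for r in self.rounds],
                "focal_move": [r.focal_move.value for r in self.rounds],
                "other_move": [r.other_move.value for r in self.rounds],
                "outcome": [r.outcome.value for r in self.rounds],
                "focal_points": [r.focal_points for r in self.rounds],
                "other_points": [r.other_points for r in self.rounds],
            }
        )


# A decision policy maps (round_number, previous outcome from the policy's own
# perspective) to a Move; round_number starts at 1 and the previous outcome is
# None on the first round.
Policy = Callable[[int, Union[Outcome, None]], Move]


def as_policy(player) -> Callable[[int, Union[Outcome, None], float], Move]:
    """Normalize a player spec to a move function.

    ``player`` may be a :class:`MemoryOneStrategy` (from ``coopsignal.zd``),
    a fixed :class:`Move`, a scripted sequence of Moves, or any callable
    ``(round, prev_outcome) -> Move``.  Returns a function mapping
    (round, prev_outcome, uniform draw) -> Move so that the match engine can
    consume exactly one uniform draw per player per round regardless of
    whether the policy is stochastic.
    """
    # Imported here to avoid a circular import at module load.
    from .zd import MemoryOneStrategy

    if isinstance(player, MemoryOneStrategy):

        def move(rnd: int, prev: Outcome | None, u: float) -> Move:
            pr = player.initial_cooperation_prob() if prev is None else player.prob(prev)
            return Move.C if u < pr else Move.D

        return move
    if isinstance(player, Move):
        fixed = player

        def move(rnd: int, prev: Outcome | None, u: float) -> Move:
            return fixed

        return move
    if isinstance(player, (list, tuple)):
        script: Sequence[Move] = [Move(m) for m in player]

        def move(rnd: int, prev: Outcome | None, u: float) -> Move:
            return script[rnd - 1]

        return move
    if callable(player):

        def move(rnd: int, prev: Outcome | None, u: float) -> Move:
            return Move(player(rnd, prev))

        return move
    raise TypeError(f"cannot interpret {player!r} as a decision policy")


def play_match(focal, other, n_rounds: int, seed: int | None = None) -> MatchRecord:
    """Play an iterated match and return the full round log.

    Parameters
    ----------
    focal, other
        Decision policies (memory-one strategy, fixed Move, scripted move
        sequence, or callable).  The engine is symmetric: "focal" is simply
        whichever player is passed first.
    n_rounds : int
        Number of rounds, >= 1.
    seed : int, optional
        Seed for the match's random generator.  One generator drives the
        whole match; two uniforms are consumed per round, focal's before
        the other's, so identical seeds give bitwise-identical records.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    m = PayoffMatrix.study()
    focal_move = as_policy(focal)
    other_move = as_policy(other)
    rng = np.random.default_rng(seed)
    draws = rng.random(2 * n_rounds)
    rounds: list[RoundResult] = []
    prev_f: Outcome | None = None
    prev_o: Outcome | None = None
    for t in range(1, n_rounds + 1):
        mf = focal_move(t, prev_f, draws[2 * t - 2])
        mo = other_move(t, prev_o, draws[2 * t - 1])
        out = outcome_of(mf, mo)
        pf, po = payoffs_of(out, m)
        rounds.append(RoundResult(t, mf, mo, out, pf, po))
        prev_f = out
        prev_o = flip_outcome(out)
    return MatchRecord(rounds)


def simulate_outcome_counts(focal, other, n_rounds: int, seed: int | None = None) -> np.ndarray:
    """Outcome counts (CC, CD, DC, DD) of a match, without the round log.

    Consumes the identical random stream as :func:`play_match` (same seed,
    same per-round draw order), so the two agree round for round; this
    counting mode exists for long-horizon frequency estimation where
    materializing millions of round records is pointless.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    from .zd import MemoryOneStrategy

    if not (isinstance(focal, MemoryOneStrategy) and isinstance(other, MemoryOneStrategy)):
        rec = play_match(focal, other, n_rounds, seed)
        return rec.outcome_counts()
    # Fast path: both players memory-one.  State = outcome index from the
    # focal perspective; co-player conditions on the flipped outcome.
    pf = [float(x) for x in focal.p]
    po = [float(x) for x in other.p]
    flip = (0, 2, 1, 3)
    rng = np.random.default_rng(seed)
    draws = rng.random(2 * n_rounds)
    counts = [0, 0, 0, 0]
    a = float(focal.initial_cooperation_prob())
    b = float(other.initial_cooperation_prob())
    state = 0
    for t in range(n_rounds):
        cf = draws[2 * t] < a
        co = draws[2 * t + 1] < b
        state = (0 if cf else 2) + (0 if co else 1)
        counts[state] += 1
        a = pf[state]
        b = po[flip[state]]
    return np.asarray(counts, dtype=np.int64)
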