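"""Outcome-contingent emotion display policy of the counterpart.

The counterpart reacts to each round outcome with one of four facial
expressions.  Two orientations are distinguished:

* cooperative — joy after mutual cooperation, regret after exploiting the
  participant, anger after being exploited, neutral otherwise;
* competitive — regret after mutual cooperation (a missed chance to
  exploit), joy after exploiting the participant, anger after being
  exploited, neutral otherwise.

Outcomes are encoded from the counterpart strategist's perspective before
lookup: "after exploiting the participant" is DC (strategist defected,
participant cooperated).  The two orientations differ only on CC and DC,
so any round sequence containing only CD/DD outcomes is uninformative
about orientation.  No expression precedes round 1 — displays react to
outcomes.
"""

from __future__ import annotations

import enum

from .game import Outcome

__all__ = ["Orientation", "Expression", "SelfReportEmotion", "express", "expression_table"]


class Orientation(str, enum.Enum):
    COOPERATIVE = "cooperative"
    COMPETITIVE = "competitive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Expression(str, enum.Enum):
    """Displays available to the counterpart's virtual face."""

    JOY = "joy"
    REGRET = "regret"
    ANGER = "anger"
    NEUTRAL = "neutral"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SelfReportEmotion(str, enum.Enum):
    """Emotions participants may self-report (includes sadness; displays do not)."""

    JOY = "joy"
    SADNESS = "sadness"
    ANGER = "anger"
    REGRET = "regret"
    NEUTRAL = "neutral"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_TABLES: dict[Orientation, dict[Outcome, Expression]] = {
    Orientation.COOPERATIVE: {
        Outcome.CC: Expression.JOY,
        Outcome.CD: Expression.ANGER,
        Outcome.DC: Expression.REGRET,
        Outcome.DD: Expression.NEUTRAL,
    },
    Orientation.COMPETITIVE: {
        Outcome.CC: Expression.REGRET,
        Outcome.CD: Expression.ANGER,
        Outcome.DC: Expression.JOY,
        Outcome.DD: Expression.NEUTRAL,
    },
}


def express(orientation: Orientation, outcome: Outcome) -> Expression:
    """Expression displayed after ``outcome`` (counterpart perspective)."""
    return _TABLES[Orientation(orientation)][Outcome(outcome)]


def expression_table(orientation: Orientation) -> dict[Outcome, Expression]:
    """The full outcome-to-expression mapping for one orientation."""
    return dict(_TABLES[Orientation(orientation)])
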