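"""Synthetic participant cohorts for the iterated prisoner's dilemma task.

The generator emulates the structure of the behavioral study's trial data:
a 2 x 2 between-subjects design (counterpart strategy: extortion vs
generosity; emotion orientation: cooperative vs competitive), ~85
participants per cell, 20 rounds each.  The counterpart side is exact — it
plays the cell's zero-determinant strategy and displays the cell's
expression policy.  The participant side is a logistic memory-one model
with covariates:

    logit P(cooperate) = b0 + b_strat * [generosity]
                         + b_emo_gen * [generosity & cooperative display]
                         + b_emo_ext * [extortion & cooperative display]
                         + b_recip  * [counterpart cooperated last round]
                         + b_expect * (previous expectation rating - 50)/50
                         + b_first  * [round 1] + b_last * [last round] + u_i

with a participant random intercept u_i ~ N(0, sigma_u).  The defaults
encode the qualitative findings the statistical pipeline is meant to
detect: a strategy effect much larger than the emotion effect, an emotion
effect only under generosity (b_emo_ext = 0), first-round cooperation
high with an end-game drop, and cooperation reciprocating the
counterpart's previous move.  The ``b_expect`` path makes decisions
respond to the participant's own expectation of counterpart cooperation
(reported at the end of the previous round), which is what lets the
mediation analyses find expectation carrying condition effects: zeroing
``b_strat``/``b_emo_*``/``b_recip`` while keeping ``b_expect`` > 0 yields
a cohort whose condition effect flows entirely through the expectation
mediator.

Mediators: the per-round expectation-of-cooperation rating is a clipped
linear function of the counterpart's cooperation frequency so far and the
display orientation, plus Gaussian noise on a 0-100 scale; the self-report
emotion is drawn from a softmax whose joy score increases with the round
payoff.  Post-task ratings (mental demand, genuineness of the displays)
are clipped-rounded normals on a 1-7 scale whose defaults mirror the
direction observed in the study (genuineness higher under generosity).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .emotions import Orientation, express
from .game import OUTCOMES
from .zd import EXTORTION, GENEROSITY, MemoryOneStrategy

__all__ = ["CohortConfig", "participant_coop_prob", "generate_cohort"]

STRATEGIES: dict[str, MemoryOneStrategy] = {
    "extortion": EXTORTION,
    "generosity": GENEROSITY,
}

#: Participant-perspective payoffs over (CC, CD, DC, DD), study matrix.
_PARTICIPANT_PAYOFF = np.array([5.0, 2.0, 7.0, 3.0])

_SELF_REPORTS = ("joy", "sadness", "anger", "regret", "neutral")


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Behavioral coefficients are on the log-odds scale.  The defaults are
    calibrated so that, with n_per_cell=85, the strategy main effect on
    cooperation rate has partial eta-squared near 0.2 (the study reports
    0.225) while the emotion effect is an order of magnitude smaller and
    confined to the generosity cells.
    """

    n_per_cell: int = 85
    n_rounds: int = 20
    # participant decision model (log-odds)
    b0: float = -1.0
    b_strat: float = 0.15
    b_emo_gen: float = 0.45
    b_emo_ext: float = 0.0
    b_recip: float = 0.7
    b_expect: float = 0.4
    b_first: float = 1.8
    b_last: float = -0.8
    sigma_u: float = 0.8
    # expectation-rating model (0-100 scale)
    a_base: float = 10.0
    a_exp: float = 65.0
    a_strat: float = 0.0
    a_emo: float = 4.0
    exp_noise_sd: float = 15.0
    # self-report model
    emotion_temperature: float = 1.0
    # post-task ratings (1-7 ordinal): (generosity mean, extortion mean, sd)
    demand_means: tuple[float, float] = (3.5, 3.05)
    demand_sd: float = 1.4
    genuine_means: tuple[float, float] = (4.94, 3.98)
    genuine_sd: float = 1.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        for name in ("sigma_u", "exp_noise_sd", "demand_sd", "genuine_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        coefs = (self.b0, self.b_strat, self.b_emo_gen, self.b_emo_ext,
                 self.b_recip, self.b_expect, self.b_first, self.b_last)
        if not np.all(np.isfinite(coefs)):
            raise ValueError("behavioral coefficients must be finite")

    @classmethod
    def null(cls, n_per_cell: int = 85, seed: int | None = None) -> "CohortConfig":
        """Zero-effect configuration: participant behavior independent of
        condition and round.  Used for type-I-error calibration."""
        return cls(
            n_per_cell=n_per_cell,
            b0=0.0,
            b_strat=0.0,
            b_emo_gen=0.0,
            b_emo_ext=0.0,
            b_recip=0.0,
            b_expect=0.0,
            b_first=0.0,
            b_last=0.0,
            seed=seed,
        )

    @classmethod
    def mediation_chain(cls, n_per_cell: int = 85, seed: int | None = None) -> "CohortConfig":
        """Clean-mediation scenario: the condition effect on cooperation flows
        entirely through the expectation rating.

        All direct behavioral paths (b_strat, b_emo_*, b_recip) are zero;
        expectations are driven mostly by the inference-from-strategy loading
        (exogenous given condition) plus a small realized-history loading,
        and behavior responds to expectation (b_expect > 0).  With this
        configuration the mediation analysis should find a nonzero indirect
        effect through expectation and a direct effect near zero.
        """
        return cls(
            n_per_cell=n_per_cell,
            b_strat=0.0,
            b_emo_gen=0.0,
            b_emo_ext=0.0,
            b_recip=0.0,
            b_expect=2.2,
            sigma_u=0.3,
            a_base=30.0,
            a_exp=0.5,
            a_strat=35.0,
            exp_noise_sd=18.0,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["demand_means"] = list(self.demand_means)
        d["genuine_means"] = list(self.genuine_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("demand_means", "genuine_means"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def participant_coop_prob(
    is_generosity,
    is_cooperative_emotion,
    round_number,
    counterpart_cooperated_last,
    random_intercept,
    config: CohortConfig,
    previous_expectation=50.0,
):
    """Cooperation probability of the participant model (vectorizable).

    ``counterpart_cooperated_last`` must be 0 on round 1 (there is no
    previous round; the reciprocity term is inactive).
    ``previous_expectation`` is the 0-100 rating reported at the end of
    the previous round; the midpoint 50 (the round-1 default) makes the
    expectation term vanish.
    """
    g = np.asarray(is_generosity, dtype=float)
    e = np.asarray(is_cooperative_emotion, dtype=float)
    rnd = np.asarray(round_number)
    lp = (
        config.b0
        + config.b_strat * g
        + config.b_emo_gen * g * e
        + config.b_emo_ext * (1 - g) * e
        + config.b_recip * np.asarray(counterpart_cooperated_last, dtype=float)
        + config.b_expect * (np.asarray(previous_expectation, dtype=float) - 50.0) / 50.0
        + config.b_first * (rnd == 1)
        + config.b_last * (rnd == config.n_rounds)
        + np.asarray(random_intercept, dtype=float)
    )
    return 1.0 / (1.0 + np.exp(-lp))


def _self_report_logits(config: CohortConfig) -> np.ndarray:
    """(4 outcomes x 5 emotions) score matrix for the self-report softmax.

    Joy rises with the participant's round payoff; sadness falls with it;
    anger and regret peak after being exploited (outcome CD from the
    participant's perspective); neutral is a constant alternative.
    """
    tau = config.emotion_temperature
    pay = _PARTICIPANT_PAYOFF
    mid = 4.25  # payoff midpoint of the study matrix
    logits = np.empty((4, 5))
    logits[:, 0] = tau * (pay - mid)          # joy
    logits[:, 1] = 0.6 * tau * (mid - pay)    # sadness
    logits[:, 2] = np.where(np.arange(4) == 1, 1.2 * tau, -1.0)  # anger after CD
    logits[:, 3] = np.where(np.arange(4) == 1, 0.5 * tau, -1.0)  # regret after CD
    logits[:, 4] = 0.3                         # neutral
    return logits


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort; returns (trial table, post-task table).

    The same seed yields byte-identical tables.  Counterpart moves follow
    the cell's memory-one strategy exactly; expressions follow the cell's
    orientation policy.  Outcomes in the trial table are encoded from the
    participant's perspective.
    """
    rng = np.random.default_rng(config.seed)
    cells = [
        ("extortion", "cooperative"),
        ("extortion", "competitive"),
        ("generosity", "cooperative"),
        ("generosity", "competitive"),
    ]
    n = config.n_per_cell
    N = 4 * n
    strategy = np.repeat([c[0] for c in cells], n)
    emotion = np.repeat([c[1] for c in cells], n)
    is_gen = (strategy == "generosity").astype(float)
    is_coop_emo = (emotion == "cooperative").astype(float)
    pid = np.array([f"P{i:04d}" for i in range(1, N + 1)])

    u = rng.normal(0.0, config.sigma_u, N)

    # counterpart strategy probabilities per participant, indexed by the
    # previous outcome from the *counterpart's* perspective
    p_ext = np.array([float(x) for x in EXTORTION.p])
    p_gen = np.array([float(x) for x in GENEROSITY.p])
    cp_probs = np.where(is_gen[:, None] == 1.0, p_gen[None, :], p_ext[None, :])
    cp_initial_coop = np.where(is_gen == 1.0, 1.0, 0.0)  # generosity starts C

    # expression lookup: rows = orientation (0 coop, 1 comp), cols = outcome
    # index from the counterpart's perspective
    expr_lookup = np.array(
        [
            [express(Orientation.COOPERATIVE, o).value for o in OUTCOMES],
            [express(Orientation.COMPETITIVE, o).value for o in OUTCOMES],
        ],
        dtype=object,
    )
    orient_idx = np.where(is_coop_emo == 1.0, 0, 1)

    sr_logits = _self_report_logits(config)
    sr_probs = np.exp(sr_logits - sr_logits.max(axis=1, keepdims=True))
    sr_probs /= sr_probs.sum(axis=1, keepdims=True)
    sr_cum = np.cumsum(sr_probs, axis=1)

    flip = np.array([0, 2, 1, 3])
    outcome_labels = np.array([o.value for o in OUTCOMES], dtype=object)

    part_moves = np.empty((config.n_rounds, N), dtype=object)
    cpart_moves = np.empty((config.n_rounds, N), dtype=object)
    outcomes = np.empty((config.n_rounds, N), dtype=np.int64)
    expressions = np.empty((config.n_rounds, N), dtype=object)
    self_reports = np.empty((config.n_rounds, N), dtype=object)
    expectations = np.empty((config.n_rounds, N))

    cp_coop_count = np.zeros(N)
    prev_outcome_idx = np.zeros(N, dtype=np.int64)  # participant perspective
    prev_expectation = np.full(N, 50.0)
    congruence = np.where(is_coop_emo == 1.0, 1.0, -1.0)

    for t in range(1, config.n_rounds + 1):
        u_part = rng.random(N)
        u_cp = rng.random(N)
        eps_exp = rng.normal(0.0, config.exp_noise_sd, N) if config.exp_noise_sd > 0 else np.zeros(N)
        u_sr = rng.random(N)

        if t == 1:
            coop_last = np.zeros(N)
            cp_pc = cp_initial_coop
        else:
            # counterpart cooperated last round: participant-perspective
            # outcome has second letter C, i.e. index 0 (CC) or 2 (DC)
            coop_last = np.isin(prev_outcome_idx, (0, 2)).astype(float)
            cp_state = flip[prev_outcome_idx]  # counterpart's view of last round
            cp_pc = cp_probs[np.arange(N), cp_state]

        pc = participant_coop_prob(
            is_gen, is_coop_emo, t, coop_last, u, config,
            previous_expectation=prev_expectation,
        )
        pm = u_part < pc
        cm = u_cp < cp_pc
        out_idx = np.where(pm, 0, 2) + np.where(cm, 0, 1)

        cp_coop_count += cm
        cp_freq = cp_coop_count / t

        exp_rating = np.clip(
            config.a_base
            + config.a_exp * cp_freq
            + config.a_strat * is_gen
            + config.a_emo * congruence
            + eps_exp,
            0.0,
            100.0,
        )
        sr_idx = (u_sr[:, None] > sr_cum[out_idx]).sum(axis=1)

        part_moves[t - 1] = np.where(pm, "C", "D")
        cpart_moves[t - 1] = np.where(cm, "C", "D")
        outcomes[t - 1] = out_idx
        expressions[t - 1] = expr_lookup[orient_idx, flip[out_idx]]
        self_reports[t - 1] = np.array(_SELF_REPORTS, dtype=object)[sr_idx]
        expectations[t - 1] = exp_rating
        prev_outcome_idx = out_idx
        prev_expectation = exp_rating

    trials = pd.DataFrame(
        {
            "participant_id": np.tile(pid, config.n_rounds),
            "strategy": np.tile(strategy, config.n_rounds),
            "emotion": np.tile(emotion, config.n_rounds),
            "round": np.repeat(np.arange(1, config.n_rounds + 1), N),
            "participant_move": part_moves.ravel(),
            "counterpart_move": cpart_moves.ravel(),
            "outcome": outcome_labels[outcomes.ravel()],
            "counterpart_expression": expressions.ravel(),
            "self_report": self_reports.ravel(),
            "expectation_rating": np.round(expectations.ravel(), 6),
        }
    ).sort_values(["participant_id", "round"], kind="stable").reset_index(drop=True)

    demand_mu = np.where(is_gen == 1.0, config.demand_means[0], config.demand_means[1])
    genuine_mu = np.where(is_gen == 1.0, config.genuine_means[0], config.genuine_means[1])
    demand = np.clip(np.rint(rng.normal(demand_mu, config.demand_sd)), 1, 7).astype(int)
    genuine = np.clip(np.rint(rng.normal(genuine_mu, config.genuine_sd)), 1, 7).astype(int)
    post = pd.DataFrame(
        {
            "participant_id": pid,
            "strategy": strategy,
            "emotion": emotion,
            "mental_demand": demand,
            "genuineness": genuine,
        }
    )
    return trials, post
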