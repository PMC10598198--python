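"""Domain types, normalisation conventions, grids, and the mood-induction session structure.

All quantities are handled internally in normalised units: the large reward
is 1 (30 euro at display scale), small rewards are fractions of it, and every
cost is expressed as a fraction of its type-specific maximum (one year of
delay, a 100% chance of losing 10 euro, 12 flights of stairs, 12 pages of
text to copy). Euro/day/flight/line scales only appear at the I/O boundary,
through :func:`offer_to_physical` and its inverse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BIG_REWARD_EUR = 30.0
#: risk trials can lose 10 euro, i.e. one third of the large reward
RISK_LOSS_FRAC = 10.0 / 30.0
MAX_DELAY_DAYS = 365
MAX_FLIGHTS = 12
LINES_PER_PAGE = 25
MAX_PAGES = 12  # chosen by symmetry with the 12 flights of stairs; configurable
MAX_LINES = MAX_PAGES * LINES_PER_PAGE

N_GRID = 50
TRIALS_PER_SESSION = 128
EPISODE_LEN = 18
TRANSITION_LEN = 7
N_EPISODES_PER_VALENCE = 2


class CostType(enum.Enum):
    """The four cost dimensions traded against monetary reward."""

    RISK = "risk"
    DELAY = "delay"
    PHYSICAL_EFFORT = "physical_effort"
    MENTAL_EFFORT = "mental_effort"

    def __str__(self) -> str:  # stable serialization label
        return self.value


COST_TYPES = tuple(CostType)


class Condition(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    TRANSITION = "transition"

    def __str__(self) -> str:
        return self.value


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


#: proportion of incorrect quiz answers given positive feedback, per condition
FEEDBACK_BIAS = {
    Condition.POSITIVE: 0.50,
    Condition.TRANSITION: 0.25,
    Condition.NEGATIVE: 0.0,
}

#: default correct-answer probability per condition (question-difficulty tiers)
P_CORRECT = {
    Condition.POSITIVE: 0.506,
    Condition.TRANSITION: 0.358,
    Condition.NEGATIVE: 0.216,
}


@dataclass(frozen=True)
class Offer:
    """One binary choice: small uncostly reward vs the fixed large reward at a cost.

    Parameters
    ----------
    cost_type : CostType
    r : float
        Small-reward magnitude as a fraction of the 30-euro large reward,
        in (0, 1).
    C : float
        Cost level as a fraction of the cost-type maximum, in (0, 1].
    loss : float
        Amount at stake in reward units (risk only; 10 euro -> 1/3).
    costly_side : Side
        Screen side of the costly option (counterbalancing bookkeeping).
    """

    cost_type: CostType
    r: float
    C: float
    loss: float = 0.0
    costly_side: Side = Side.LEFT

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"small reward fraction must be in (0,1), got {self.r}")
        if not 0.0 < self.C <= 1.0:
            raise ValueError(f"cost level must be in (0,1], got {self.C}")
        if self.loss < 0.0:
            raise ValueError("loss must be nonnegative")
        if self.cost_type is not CostType.RISK and self.loss != 0.0:
            raise ValueError("loss is only defined for risk offers")

    @property
    def win_probability(self) -> float:
        """P = 1 - C for risk offers (cost level is the probability of losing)."""
        if self.cost_type is not CostType.RISK:
            raise ValueError("win_probability is only defined for risk offers")
        return 1.0 - self.C


def make_offer(cost_type: CostType, r: float, C: float, costly_side: Side = Side.LEFT) -> Offer:
    """Build an :class:`Offer`, filling in the fixed 10-euro stake for risk."""
    loss = RISK_LOSS_FRAC if cost_type is CostType.RISK else 0.0
    return Offer(cost_type=cost_type, r=r, C=C, loss=loss, costly_side=costly_side)


@dataclass(frozen=True)
class GridSpec:
    """The 50 x 50 reward-by-cost lattice on which offers live.

    Cost levels run from 2% to 100% of the cost-type maximum; reward levels
    from 0.10 to 29.90 euro, as fractions of 30 euro.
    """

    cost_levels: np.ndarray
    reward_levels: np.ndarray

    def nearest_reward(self, r: float) -> float:
        """Snap a reward fraction to the nearest grid level; ties go to the lower level."""
        r = float(np.clip(r, self.reward_levels[0], self.reward_levels[-1]))
        d = np.abs(self.reward_levels - r)
        # argmin returns the first (lower) index on exact ties
        return float(self.reward_levels[int(np.argmin(d))])

    def nearest_cost_index(self, C: float) -> int:
        C = float(np.clip(C, self.cost_levels[0], self.cost_levels[-1]))
        return int(np.argmin(np.abs(self.cost_levels - C)))


def build_grids() -> GridSpec:
    """Return the canonical 50-level cost and reward grids."""
    cost = np.linspace(0.02, 1.0, N_GRID)
    reward = np.linspace(0.1 / 30.0, 29.9 / 30.0, N_GRID)
    return GridSpec(cost_levels=cost, reward_levels=reward)


@dataclass(frozen=True)
class TrialSlot:
    index: int
    condition: Condition
    feedback_bias: float
    p_correct: float
    cost_type: CostType


@dataclass(frozen=True)
class SessionSchedule:
    """One 128-trial session: 2 positive + 2 negative 18-trial episodes, each
    flanked before and after by its own 7-trial transition block."""

    trials: tuple[TrialSlot, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "condition": [str(t.condition) for t in self.trials],
                "feedback_bias": [t.feedback_bias for t in self.trials],
                "p_correct": [t.p_correct for t in self.trials],
                "cost_type": [str(t.cost_type) for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cost_type_sequence(n_trials: int, rng: np.random.Generator) -> list[CostType]:
    """Pseudo-random cost-type order: every aligned block of 4 trials contains
    each type once, and the same type never appears on two adjacent trials.

    The boundary constraint is enforced by rejection-resampling each block
    permutation, which is unbiased among the valid orders.
    """
    assert n_trials % 4 == 0
    seq: list[CostType] = []
    for _ in range(n_trials // 4):
        while True:
            block = list(rng.permutation(4))
            if not seq or COST_TYPES[block[0]] is not seq[-1]:
                break
        seq.extend(COST_TYPES[i] for i in block)
    return seq


def make_session_schedule(
    seed: int | np.random.Generator,
    p_correct: dict[Condition, float] | None = None,
) -> SessionSchedule:
    """Generate one seeded session schedule.

    Episode valence order (2 positive, 2 negative) and the cost-type sequence
    are drawn from the seeded RNG; the block structure itself is fixed by
    design: [7 transition, 18 episode, 7 transition] x 4 = 128 trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pc = dict(P_CORRECT if p_correct is None else p_correct)

    valences = [Condition.POSITIVE] * N_EPISODES_PER_VALENCE + [Condition.NEGATIVE] * N_EPISODES_PER_VALENCE
    order = rng.permutation(len(valences))
    conditions: list[Condition] = []
    for i in order:
        conditions.extend([Condition.TRANSITION] * TRANSITION_LEN)
        conditions.extend([valences[i]] * EPISODE_LEN)
        conditions.extend([Condition.TRANSITION] * TRANSITION_LEN)
    assert len(conditions) == TRIALS_PER_SESSION

    cost_seq = _cost_type_sequence(TRIALS_PER_SESSION, rng)
    slots = tuple(
        TrialSlot(
            index=i,
            condition=cond,
            feedback_bias=FEEDBACK_BIAS[cond],
            p_correct=pc[cond],
            cost_type=ct,
        )
        for i, (cond, ct) in enumerate(zip(conditions, cost_seq))
    )
    return SessionSchedule(trials=slots)


@dataclass(frozen=True)
class PhysicalOffer:
    """An offer in the units shown to participants."""

    cost_type: CostType
    small_reward_eur: float
    quantity: float
    unit: str
    description: str


def _round_half_up(x: float, ndigits: int = 2) -> float:
    scale = 10**ndigits
    return float(np.floor(x * scale + 0.5) / scale)


def offer_to_physical(offer: Offer) -> PhysicalOffer:
    """Map a normalised offer to euros and physical cost units.

    Risk -> percent chance of losing 10 euro; delay -> days out of 365;
    physical effort -> flights of stairs out of 12; mental effort -> lines of
    text out of 300 (12 pages of 25 lines).
    """
    eur = _round_half_up(offer.r * BIG_REWARD_EUR)
    ct = offer.cost_type
    if ct is CostType.RISK:
        pct = _round_half_up(offer.C * 100.0, 0)
        return PhysicalOffer(ct, eur, pct, "%", f"{pct:.0f}% risk of losing 10€")
    if ct is CostType.DELAY:
        days = round(offer.C * MAX_DELAY_DAYS)
        return PhysicalOffer(ct, eur, days, "days", f"{days} days until payment")
    if ct is CostType.PHYSICAL_EFFORT:
        flights = _round_half_up(offer.C * MAX_FLIGHTS, 2)
        return PhysicalOffer(ct, eur, flights, "flights", f"{flights:g} flights of stairs")
    lines = round(offer.C * MAX_LINES)
    pages = lines / LINES_PER_PAGE
    return PhysicalOffer(ct, eur, lines, "lines", f"{lines} lines ({pages:g} pages) to copy")


def physical_to_offer(cost_type: CostType, small_reward_eur: float, quantity: float) -> Offer:
    """Inverse of :func:`offer_to_physical` (round-trips within grid resolution)."""
    r = small_reward_eur / BIG_REWARD_EUR
    if cost_type is CostType.RISK:
        C = quantity / 100.0
    elif cost_type is CostType.DELAY:
        C = quantity / MAX_DELAY_DAYS
    elif cost_type is CostType.PHYSICAL_EFFORT:
        C = quantity / MAX_FLIGHTS
    else:
        C = quantity / MAX_LINES
    return make_offer(cost_type, r, C)
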