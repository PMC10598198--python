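"""The discount-function family and softmax choice rules.

Subjective value of the costly option, per cost type (normalised units,
large reward Rew = 1):

* risk:            V = k_Rew * Rew * P - k_R * L * (1 - P)**g_R,  P = 1 - C
* delay:           V = k_Rew * Rew * exp(-k_D * D**g_D)
* physical effort: V = k_Rew * Rew - k_PE * PE**g_PE
* mental effort:   V = k_Rew * Rew - k_ME * ME**g_ME

The uncostly option is worth k_Rew * r. Choice probability is a softmax of
the decision value DV = V(costly) - V(uncostly),

    P(costly) = sigmoid(b0 + b1 * DV),

optionally modulated by the trial's (z-scored) mood rating m, either
additively on the bias, b0 * (1 + b_mood * m), or multiplicatively on the
reward weight, k_Rew * (1 + b_mood * m).

The model space crosses {reward weight free/fixed} x {cost powers
free/fixed} x {b1 absent/shared/specific} x {b0 absent/shared/specific},
giving 36 candidates (mood off). Fixed powers are 1 for risk and delay and
2 for the two efforts; an absent temperature means b1 fixed at 1, an absent
bias means b0 = 0.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import CostType, COST_TYPES, Offer


class Scheme(enum.Enum):
    """How a softmax parameter varies over cost types."""

    ABSENT = "absent"
    SHARED = "shared"
    SPECIFIC = "specific"


class MoodVariant(enum.Enum):
    NONE = "none"
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"


_SCHEME_CODE = {Scheme.ABSENT: "0", Scheme.SHARED: "S", Scheme.SPECIFIC: "4"}
_MOOD_CODE = {MoodVariant.NONE: "0", MoodVariant.ADDITIVE: "A", MoodVariant.MULTIPLICATIVE: "M"}

#: fixed cost-power exponents when the powers are not free parameters
FIXED_GAMMA = {
    CostType.RISK: 1.0,
    CostType.DELAY: 1.0,
    CostType.PHYSICAL_EFFORT: 2.0,
    CostType.MENTAL_EFFORT: 2.0,
}


@dataclass(frozen=True)
class ModelSpec:
    """One member of the discount/softmax model family."""

    has_reward_weight: bool = True
    has_power: bool = False
    temperature_scheme: Scheme = Scheme.SPECIFIC
    bias_scheme: Scheme = Scheme.SPECIFIC
    mood_variant: MoodVariant = MoodVariant.NONE

    @property
    def n_free_params(self) -> int:
        """ABSENT/SHARED/SPECIFIC contribute 0/1/4; +1 for k_Rew; +4 for free
        powers; the four cost weights are always free; +1 for a mood weight."""
        n = 4  # k_R, k_D, k_PE, k_ME
        n += 1 if self.has_reward_weight else 0
        n += 4 if self.has_power else 0
        n += {Scheme.ABSENT: 0, Scheme.SHARED: 1, Scheme.SPECIFIC: 4}[self.temperature_scheme]
        n += {Scheme.ABSENT: 0, Scheme.SHARED: 1, Scheme.SPECIFIC: 4}[self.bias_scheme]
        n += 0 if self.mood_variant is MoodVariant.NONE else 1
        return n

    @property
    def code(self) -> str:
        """Short string code used in result tables and on the command line."""
        return (
            f"kRew{int(self.has_reward_weight)}"
            f"+pow{int(self.has_power)}"
            f"+b1{_SCHEME_CODE[self.temperature_scheme]}"
            f"+b0{_SCHEME_CODE[self.bias_scheme]}"
            f"+mood{_MOOD_CODE[self.mood_variant]}"
        )

    @classmethod
    def from_code(cls, code: str) -> "ModelSpec":
        scheme_rev = {v: k for k, v in _SCHEME_CODE.items()}
        mood_rev = {v: k for k, v in _MOOD_CODE.items()}
        try:
            krew, pw, b1, b0, mood = code.split("+")
            return cls(
                has_reward_weight=bool(int(krew.removeprefix("kRew"))),
                has_power=bool(int(pw.removeprefix("pow"))),
                temperature_scheme=scheme_rev[b1.removeprefix("b1")],
                bias_scheme=scheme_rev[b0.removeprefix("b0")],
                mood_variant=mood_rev[mood.removeprefix("mood")],
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"unparseable model code {code!r}") from exc

    def with_mood(self, variant: MoodVariant = MoodVariant.ADDITIVE) -> "ModelSpec":
        return ModelSpec(
            self.has_reward_weight, self.has_power, self.temperature_scheme, self.bias_scheme, variant
        )


#: the model that won the group-level comparison: shared reward weight, fixed
#: powers, cost-specific temperature and bias (13 free parameters)
WINNING_SPEC = ModelSpec(
    has_reward_weight=True,
    has_power=False,
    temperature_scheme=Scheme.SPECIFIC,
    bias_scheme=Scheme.SPECIFIC,
    mood_variant=MoodVariant.NONE,
)

#: the winning model augmented with the additive mood bias (14 parameters)
WINNING_MOOD_SPEC = WINNING_SPEC.with_mood(MoodVariant.ADDITIVE)


def enumerate_model_space() -> list[ModelSpec]:
    """The 36 mood-free candidates, in canonical order."""
    schemes = (Scheme.ABSENT, Scheme.SHARED, Scheme.SPECIFIC)
    return [
        ModelSpec(hrw, hp, ts, bs, MoodVariant.NONE)
        for hrw, hp, ts, bs in itertools.product((False, True), (False, True), schemes, schemes)
    ]


@dataclass
class DiscountParams:
    """A full parameter setting for one :class:`ModelSpec`.

    Values are stored expanded per cost type; shared/fixed schemes simply
    hold equal (or unit/zero) entries, so evaluation never branches on the
    scheme.
    """

    k_rew: float = 1.0
    k_cost: dict[CostType, float] = field(default_factory=lambda: {t: 1.0 for t in COST_TYPES})
    gamma: dict[CostType, float] = field(default_factory=lambda: dict(FIXED_GAMMA))
    beta1: dict[CostType, float] = field(default_factory=lambda: {t: 1.0 for t in COST_TYPES})
    beta0: dict[CostType, float] = field(default_factory=lambda: {t: 0.0 for t in COST_TYPES})
    beta_mood: float = 0.0

    def validate(self) -> None:
        if self.k_rew <= 0:
            raise ValueError("k_rew must be positive")
        for t in COST_TYPES:
            if self.k_cost[t] <= 0 or self.gamma[t] <= 0 or self.beta1[t] <= 0:
                raise ValueError(f"k, gamma, beta1 must be positive for {t}")


def value_costly(offer: Offer, params: DiscountParams, mood_z: float | None = None,
                 mood_variant: MoodVariant = MoodVariant.NONE) -> float:
    """Subjective value of the costly option under the discount functions.

    With the multiplicative mood variant, the reward weight is scaled by
    (1 + beta_mood * mood_z) before valuation.
    """
    if not np.isfinite(offer.C) or offer.C < 0:
        raise ValueError("cost must be finite and nonnegative")
    k_rew = params.k_rew
    if mood_variant is MoodVariant.MULTIPLICATIVE:
        if mood_z is None:
            raise ValueError("multiplicative mood variant requires mood_z")
        k_rew = k_rew * (1.0 + params.beta_mood * mood_z)
    t = offer.cost_type
    k, g = params.k_cost[t], params.gamma[t]
    rew = 1.0
    if t is CostType.RISK:
        p_win = 1.0 - offer.C
        if not 0.0 <= p_win <= 1.0:
            raise ValueError("win probability outside [0,1]")
        return k_rew * rew * p_win - k * offer.loss * (1.0 - p_win) ** g
    if t is CostType.DELAY:
        return k_rew * rew * np.exp(-k * offer.C**g)
    return k_rew * rew - k * offer.C**g


def value_uncostly(offer: Offer, params: DiscountParams, mood_z: float | None = None,
                   mood_variant: MoodVariant = MoodVariant.NONE) -> float:
    """Value of the sure/immediate/effortless small reward: k_Rew * r."""
    k_rew = params.k_rew
    if mood_variant is MoodVariant.MULTIPLICATIVE:
        if mood_z is None:
            raise ValueError("multiplicative mood variant requires mood_z")
        k_rew = k_rew * (1.0 + params.beta_mood * mood_z)
    return k_rew * offer.r


def decision_value(offer: Offer, params: DiscountParams, mood_z: float | None = None,
                   mood_variant: MoodVariant = MoodVariant.NONE) -> float:
    """DV = V(costly) - V(uncostly)."""
    return value_costly(offer, params, mood_z, mood_variant) - value_uncostly(
        offer, params, mood_z, mood_variant
    )


def choice_probability(offer: Offer, params: DiscountParams, spec: ModelSpec,
                       mood_z: float | None = None) -> float:
    """P(costly) under the spec's softmax, with the spec's mood variant.

    additive: sigmoid(b0 * (1 + b_mood * m) + b1 * DV); multiplicative: the
    mood scales k_Rew inside DV and the bias is untouched.
    """
    variant = spec.mood_variant
    if variant is not MoodVariant.NONE and mood_z is None:
        raise ValueError(f"mood variant {variant} requires mood_z")
    if mood_z is not None and not np.isfinite(mood_z):
        raise ValueError("mood_z must be finite")
    t = offer.cost_type
    b0, b1 = params.beta0[t], params.beta1[t]
    if variant is MoodVariant.MULTIPLICATIVE:
        dv = decision_value(offer, params, mood_z, variant)
    else:
        dv = decision_value(offer, params)
        if variant is MoodVariant.ADDITIVE:
            b0 = b0 * (1.0 + params.beta_mood * mood_z)
    return float(expit(b0 + b1 * dv))


def simulate_choice(offer: Offer, params: DiscountParams, spec: ModelSpec,
                    mood_z: float | None, rng: np.random.Generator) -> bool:
    """Draw one choice; True means the costly option was taken."""
    p = choice_probability(offer, params, spec, mood_z)
    return bool(rng.random() < p)
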