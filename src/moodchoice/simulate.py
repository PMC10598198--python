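"""Synthetic agents and closed-loop session simulation.

An agent is a full parameter setting of the discount/softmax family plus a
mood generator and an RT generator. Sessions reproduce the experimental
design: 128 quiz-choice-rating trials, with 18-trial positive/negative
mood-induction episodes flanked by 7-trial transitions, condition-dependent
question difficulty and feedback bias, a mood trace driven by the feedback
sequence, and choices generated by the (optionally mood-biased) softmax on
offers delivered by the OTG, grid or random sampler.

Because feedback and mood do not depend on the agent's economic choices,
sessions are simulated in two passes: the feedback and mood trace first
(which also fixes the per-session z-scored mood used by the additive bias,
matching how ratings are z-scored at analysis time), then the closed
offer-choice loop.

The mood generator is a leaky integrator — the experiment only measures
mood, so any generator is a modelling choice here — with a stronger push
from negative than positive feedback, reproducing the asymmetry of the
induction. The RT generator shortens responses as the (bias-inclusive)
evidence toward the chosen option grows; it exists to exercise the RT
analyses, not as a mechanistic claim.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .choice_models import (FIXED_GAMMA, DiscountParams, ModelSpec, MoodVariant,
                            Scheme, WINNING_MOOD_SPEC, choice_probability,
                            decision_value)
from .core import (COST_TYPES, Condition, CostType, GridSpec, Offer,
                   SessionSchedule, Side, TrialSlot, build_grids,
                   make_offer, make_session_schedule)
from .otg import OTGConfig, OTGSampler, baseline_sampler

SAMPLERS = ("otg", "grid", "random")


@dataclass(frozen=True)
class MoodParams:
    """Leaky-integrator mood dynamics on a nominal [-1, 1] raw scale.

    m_t = decay * m_{t-1} + gain_pos * [positive] - gain_neg * [negative] + noise.
    Defaults give within-episode slopes of roughly +-0.01-0.04 z-units per
    trial, negative episodes steeper than positive ones.
    """

    decay: float = 0.85
    gain_pos: float = 0.05
    gain_neg: float = 0.09
    noise_sd: float = 0.03

    def __post_init__(self):
        if not 0.0 <= self.decay < 1.0:
            raise ValueError("decay must be in [0,1)")
        if self.gain_pos < 0 or self.gain_neg < 0 or self.noise_sd < 0:
            raise ValueError("gains and noise sd must be nonnegative")


@dataclass(frozen=True)
class RTParams:
    """Response-time generator: rt = max(base - slope * evidence, floor) * lognormal.

    evidence is the value-scale decision signal toward the chosen option,
    including the (mood-modulated) bias converted to value units; seconds.
    """

    base: float = 2.0
    value_slope: float = 0.4
    log_noise_sd: float = 0.25
    floor: float = 0.2


@dataclass
class AgentProfile:
    """Everything needed to simulate one synthetic participant."""

    params: DiscountParams
    spec: ModelSpec
    mood_params: MoodParams = MoodParams()
    rt_params: RTParams = RTParams()


@dataclass(frozen=True)
class AgentDistribution:
    """Population the agents are drawn from.

    Positive scale-free parameters (cost weights, reward weight, powers) are
    log-normal with median 1. The inverse temperature is log-normal with
    median ``beta1_median``, default 10 on the normalised value scale —
    about 1/3 per euro, a realistic choice consistency and the same scale as
    the OTG softmax temperature (a median of 1 on this scale would make
    every choice a near coin flip, since |DV| <= ~1). The bias beta0 is
    Gaussian, optionally folded positive for cohorts whose mood lever should
    not flip sign across agents; beta_mood is Gaussian.
    """

    spec: ModelSpec = WINNING_MOOD_SPEC
    log_sd: float = 0.5
    beta1_median: float = 10.0
    beta0_mean: float = 0.0
    beta0_sd: float = 1.0
    beta0_positive: bool = False
    beta_mood_mean: float = 0.6
    # population spread of the mood bias: the group-level mean 0.614 with
    # t(101) = 3.54 implies SE 0.173, i.e. a between-participant sd of
    # 0.173 * sqrt(102) ~= 1.75
    beta_mood_sd: float = 1.75
    beta_mood_positive: bool = False
    mood_params: MoodParams = MoodParams()
    rt_params: RTParams = RTParams()


def sample_agent(config: AgentDistribution, rng: np.random.Generator) -> AgentProfile:
    """Draw one agent; deterministic given the generator state."""
    spec = config.spec
    ln = lambda: float(np.exp(config.log_sd * rng.standard_normal()))
    params = DiscountParams()
    params.k_rew = ln() if spec.has_reward_weight else 1.0
    params.k_cost = {t: ln() for t in COST_TYPES}
    if spec.has_power:
        params.gamma = {t: FIXED_GAMMA[t] * ln() for t in COST_TYPES}
    else:
        params.gamma = dict(FIXED_GAMMA)
    if spec.temperature_scheme is Scheme.SPECIFIC:
        params.beta1 = {t: config.beta1_median * ln() for t in COST_TYPES}
    elif spec.temperature_scheme is Scheme.SHARED:
        v = config.beta1_median * ln()
        params.beta1 = {t: v for t in COST_TYPES}
    else:
        params.beta1 = {t: 1.0 for t in COST_TYPES}
    def draw_b0():
        v = config.beta0_mean + config.beta0_sd * rng.standard_normal()
        return abs(v) if config.beta0_positive else v
    if spec.bias_scheme is Scheme.SPECIFIC:
        params.beta0 = {t: draw_b0() for t in COST_TYPES}
    elif spec.bias_scheme is Scheme.SHARED:
        v = draw_b0()
        params.beta0 = {t: v for t in COST_TYPES}
    else:
        params.beta0 = {t: 0.0 for t in COST_TYPES}
    if spec.mood_variant is not MoodVariant.NONE:
        v = float(config.beta_mood_mean + config.beta_mood_sd * rng.standard_normal())
        params.beta_mood = abs(v) if config.beta_mood_positive else v
    return AgentProfile(params=params, spec=spec,
                        mood_params=config.mood_params, rt_params=config.rt_params)


def simulate_quiz_feedback(slot: TrialSlot, rng: np.random.Generator) -> tuple[bool, bool]:
    """One quiz outcome: (answered correctly, received positive feedback).

    Correct answers always earn positive feedback; incorrect answers are
    given positive feedback with the slot's condition-dependent bias.
    """
    correct = bool(rng.random() < slot.p_correct)
    positive = correct or bool(rng.random() < slot.feedback_bias)
    return correct, positive


def simulate_mood_trace(feedbacks: np.ndarray, mood_params: MoodParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Leaky-integrator mood from a boolean positive-feedback sequence; m_0 = 0."""
    fb = np.asarray(feedbacks, dtype=bool)
    m = np.empty(len(fb))
    prev = 0.0
    p = mood_params
    eps = p.noise_sd * rng.standard_normal(len(fb)) if p.noise_sd > 0 else np.zeros(len(fb))
    for t, f in enumerate(fb):
        prev = p.decay * prev + (p.gain_pos if f else -p.gain_neg) + eps[t]
        m[t] = prev
    return m


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def _grid_sequence_for_session(schedule: SessionSchedule, grid: GridSpec,
                               rng: np.random.Generator) -> dict[CostType, list[Offer]]:
    """Per-type lattice offers for in-session grid sampling: the smallest
    square lattice covering the type's trial count, shuffled and truncated."""
    counts = {t: sum(s.cost_type is t for s in schedule.trials) for t in CostType}
    out = {}
    for t, n in counts.items():
        m = int(np.ceil(np.sqrt(n)))
        offers = baseline_sampler("GRID", m * m, grid, rng, t)
        idx = rng.permutation(len(offers))[:n]
        out[t] = [offers[i] for i in idx]
    return out


def simulate_session(
    agent: AgentProfile,
    schedule: SessionSchedule,
    sampler: str | OTGSampler,
    rng: np.random.Generator,
    session: int = 0,
    grid: GridSpec | None = None,
    otg_config: OTGConfig = OTGConfig(),
) -> pd.DataFrame:
    """Simulate one closed-loop session; returns the canonical trial log.

    ``sampler`` is "otg", "grid" or "random", or a pre-built
    :class:`OTGSampler` (for resumed state). OTG state is fresh per session
    unless provided. The ``auc`` column holds, on OTG sessions, the area
    under the updated indifference curve of the trial's cost type.
    """
    grid = grid or build_grids()
    # pass 1: quiz feedback and mood (independent of the economic choices)
    correct = np.empty(len(schedule), dtype=bool)
    positive = np.empty(len(schedule), dtype=bool)
    for i, slot in enumerate(schedule.trials):
        correct[i], positive[i] = simulate_quiz_feedback(slot, rng)
    mood_raw = simulate_mood_trace(positive, agent.mood_params, rng)
    mood_z = _zscore(mood_raw)

    if isinstance(sampler, OTGSampler):
        otg, mode = sampler, "otg"
    elif sampler == "otg":
        otg, mode = OTGSampler(otg_config, grid), "otg"
    elif sampler in ("grid", "random"):
        otg, mode = None, sampler
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    grid_seqs = _grid_sequence_for_session(schedule, grid, rng) if mode == "grid" else None
    grid_pos = {t: 0 for t in CostType}

    spec, params = agent.spec, agent.params
    uses_mood = spec.mood_variant is not MoodVariant.NONE
    rows = []
    for i, slot in enumerate(schedule.trials):
        t = slot.cost_type
        if mode == "otg":
            offer = otg.propose(t, rng)
        elif mode == "random":
            offer = baseline_sampler("RANDOM", 1, grid, rng, t)[0]
        else:
            offer = grid_seqs[t][grid_pos[t]]
            grid_pos[t] += 1
        offer = replace(offer, costly_side=Side.LEFT if rng.random() < 0.5 else Side.RIGHT)
        m = float(mood_z[i]) if uses_mood else None
        p_costly = choice_probability(offer, params, spec, m)
        chose_costly = bool(rng.random() < p_costly)
        if mode == "otg":
            otg.record(offer, chose_costly)
            auc = otg.auc(t)
        else:
            auc = np.nan
        # evidence toward the chosen option, bias folded in on the value scale
        dv = decision_value(offer, params, m, spec.mood_variant)
        b0, b1 = params.beta0[t], params.beta1[t]
        if spec.mood_variant is MoodVariant.ADDITIVE:
            b0 = b0 * (1.0 + params.beta_mood * mood_z[i])
        evidence = dv + b0 / b1
        signed = evidence if chose_costly else -evidence
        rtp = agent.rt_params
        rt = max(rtp.base - rtp.value_slope * signed, rtp.floor) * float(
            np.exp(rtp.log_noise_sd * rng.standard_normal())
        )
        rows.append(
            {
                "session": session,
                "index": slot.index,
                "condition": str(slot.condition),
                "feedback_bias": slot.feedback_bias,
                "p_correct": slot.p_correct,
                "cost_type": str(t),
                "correct": int(correct[i]),
                "feedback_positive": int(positive[i]),
                "mood_raw": float(mood_raw[i]),
                "mood_z": float(mood_z[i]),
                "r": offer.r,
                "C": offer.C,
                "loss": offer.loss,
                "costly_side": offer.costly_side.value,
                "choice": int(chose_costly),
                "p_costly": p_costly,
                "dv": dv,
                "rt": rt,
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)


def simulate_experiment(
    agent: AgentProfile,
    rng: np.random.Generator,
    n_sessions: int = 2,
    sampler: str = "otg",
    subject: int = 0,
    otg_config: OTGConfig = OTGConfig(),
) -> pd.DataFrame:
    """Simulate a full multi-session experiment for one agent.

    Each session gets an independently randomised schedule and, for OTG, a
    fresh sampler state (no multi-session pooling).
    """
    logs = []
    for s in range(n_sessions):
        schedule = make_session_schedule(rng)
        log = simulate_session(agent, schedule, sampler, rng, session=s, otg_config=otg_config)
        logs.append(log)
    out = pd.concat(logs, ignore_index=True)
    out.insert(0, "subject", subject)
    return out


def agent_to_dict(agent: AgentProfile) -> dict:
    return {
        "spec": agent.spec.code,
        "k_rew": agent.params.k_rew,
        "k_cost": {t.value: agent.params.k_cost[t] for t in COST_TYPES},
        "gamma": {t.value: agent.params.gamma[t] for t in COST_TYPES},
        "beta1": {t.value: agent.params.beta1[t] for t in COST_TYPES},
        "beta0": {t.value: agent.params.beta0[t] for t in COST_TYPES},
        "beta_mood": agent.params.beta_mood,
        "mood_params": asdict(agent.mood_params),
        "rt_params": asdict(agent.rt_params),
    }


def agent_from_dict(d: dict) -> AgentProfile:
    params = DiscountParams(
        k_rew=d["k_rew"],
        k_cost={CostType(k): v for k, v in d["k_cost"].items()},
        gamma={CostType(k): v for k, v in d["gamma"].items()},
        beta1={CostType(k): v for k, v in d["beta1"].items()},
        beta0={CostType(k): v for k, v in d["beta0"].items()},
        beta_mood=d["beta_mood"],
    )
    return AgentProfile(
        params=params,
        spec=ModelSpec.from_code(d["spec"]),
        mood_params=MoodParams(**d["mood_params"]),
        rt_params=RTParams(**d["rt_params"]),
    )


def write_cohort(path_csv, path_agents_json, logs: pd.DataFrame, agents: list[AgentProfile]) -> None:
    """Canonical trial-log CSV plus a JSON sidecar with the generating truth."""
    logs.to_csv(path_csv, index=False)
    with open(path_agents_json, "w") as fh:
        json.dump([agent_to_dict(a) for a in agents], fh, indent=1)
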