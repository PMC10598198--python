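"""Online Trial Generation (OTG): adaptive probing of indifference points.

The indifference curve r*(C) — the small reward that makes a participant
indifferent to the large reward at cost level C — is modelled agnostically
as five edge-constrained linear pieces over the cost bins (0,.2], (.2,.4],
..., (.8,1]. With intercept bonus b0 (added to the uncostly option) and bin
slopes k1..k5, the curve in bin j is

    r*(C) = 1 - b0 - sum_{i<j} k_i * 0.2 - k_j * (C - 0.2*(j-1)).

After every observed choice the six parameters are refitted by MAP (with a
Laplace posterior) from a sliding window of the 20 most recent choices of
that cost type, under a fixed-temperature softmax likelihood. A 50 x 50
indifference map then scores every (reward, cost) grid cell by closeness of
the modelled choice probability to 50%; the next cost level is drawn from
the column-sum density of that map and paired with the reward expected to
yield indifference. Grid-lattice and uniform-random baseline samplers are
provided for performance comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import expit

from .core import CostType, GridSpec, Offer, build_grids, make_offer

N_BINS = 5
BIN_EDGES = np.arange(N_BINS) * 0.2  # left edges of the five cost bins


@dataclass(frozen=True)
class OTGConfig:
    """Tunables of the online update.

    window: number of most recent choices used when refitting (allows
    preference drift). min_obs: updates start only after this many choices.
    temperature: the fixed softmax inverse temperature of the OTG likelihood,
    on the normalised value scale (not a fitted parameter). Priors are
    Gaussian on log-parameters: slopes centred at 1 (log 0), the bonus b0
    centred just above 0.
    """

    window: int = 20
    min_obs: int = 3
    temperature: float = 10.0
    prior_loc: tuple[float, ...] = (-3.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    prior_sd: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    gtol: float = 1e-6


@dataclass(frozen=True)
class IndifferenceModel:
    """Piecewise-linear indifference curve with its (Laplace) posterior.

    The posterior lives on the log scale theta = log(b0, k1..k5); b0 and k
    are the natural-scale MAP values.
    """

    b0: float
    k: np.ndarray  # five positive bin slopes
    fixed_temperature: float = 10.0
    posterior_mean: np.ndarray | None = None  # theta scale, length 6
    posterior_cov: np.ndarray | None = None  # 6 x 6

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([[np.log(self.b0)], np.log(self.k)])


def prior_model(config: OTGConfig = OTGConfig()) -> IndifferenceModel:
    """The model implied by the prior means (slopes 1, bonus ~0)."""
    theta = np.asarray(config.prior_loc, dtype=float)
    sd = np.asarray(config.prior_sd, dtype=float)
    return IndifferenceModel(
        b0=float(np.exp(theta[0])),
        k=np.exp(theta[1:]),
        fixed_temperature=config.temperature,
        posterior_mean=theta,
        posterior_cov=np.diag(sd**2),
    )


def _bin_weights(C: np.ndarray) -> np.ndarray:
    """Weights w such that the cumulative discount at C is w @ k; shape (n, 5)."""
    C = np.atleast_1d(np.asarray(C, dtype=float))
    return np.clip(C[:, None] - BIN_EDGES[None, :], 0.0, 0.2)


def indifference_reward(C, model: IndifferenceModel):
    """r*(C): the small reward at modelled indifference (may be negative)."""
    C_arr = np.atleast_1d(np.asarray(C, dtype=float))
    if np.any(C_arr <= 0.0) or np.any(C_arr > 1.0):
        raise ValueError("cost level must lie in (0, 1]")
    r = 1.0 - model.b0 - _bin_weights(C_arr) @ model.k
    return float(r[0]) if np.isscalar(C) or np.ndim(C) == 0 else r


def indifference_score(p):
    """Closeness of a choice probability to 50%, normalised to [0, 1]."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0.0) or np.any(p_arr > 1.0):
        raise ValueError("probability must lie in [0, 1]")
    return (0.5 - np.abs(p_arr - 0.5)) / 0.5


@dataclass(frozen=True)
class IndifferenceMap:
    """Expected indifference over the 50 x 50 (reward x cost) grid."""

    grid: GridSpec
    scores: np.ndarray  # (n_reward, n_cost), each in [0, 1]
    cost_density: np.ndarray  # (n_cost,), sums to 1
    rstar: np.ndarray  # modelled indifference reward per cost column


def build_indifference_map(model: IndifferenceModel, grid: GridSpec | None = None) -> IndifferenceMap:
    """Score every grid cell by indifference under the OTG softmax."""
    grid = grid or build_grids()
    rstar = indifference_reward(grid.cost_levels, model)
    # DV of a cell = V(costly) - V(uncostly) = (1 - discount) - (r + b0) = rstar - r
    dv = rstar[None, :] - grid.reward_levels[:, None]
    p = expit(model.fixed_temperature * dv)
    scores = indifference_score(p)
    col = scores.sum(axis=0)
    return IndifferenceMap(grid=grid, scores=scores, cost_density=col / col.sum(), rstar=rstar)


def sample_next_offer(imap: IndifferenceMap, cost_type: CostType, rng: np.random.Generator) -> Offer:
    """Draw the next offer: cost from the indifference density, reward at the
    grid level closest to r*(C) (clipped into range; ties toward the lower level)."""
    j = int(rng.choice(len(imap.grid.cost_levels), p=imap.cost_density))
    C = float(imap.grid.cost_levels[j])
    r = imap.grid.nearest_reward(float(imap.rstar[j]))
    return make_offer(cost_type, r, C)


@dataclass(frozen=True)
class ChoiceObservation:
    """One observed choice, as seen by the OTG update."""

    cost_type: CostType
    r: float
    C: float
    chose_costly: bool


def _neg_log_posterior(theta, w, r, y, config):
    """Negative log posterior over theta = log(b0, k), with analytic gradient."""
    nat = np.exp(theta)
    b0, k = nat[0], nat[1:]
    # eta = temp * ((1 - w@k) - (r + b0))
    eta = config.temperature * (1.0 - w @ k - r - b0)
    p = expit(eta)
    eps = 1e-12
    nll = -np.sum(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps))
    mu = np.asarray(config.prior_loc)
    sd = np.asarray(config.prior_sd)
    nlp = nll + 0.5 * np.sum(((theta - mu) / sd) ** 2)
    # d eta / d theta = -temp * X * nat, with X = [1, w]
    X = np.column_stack([np.ones_like(r), w])
    deta = -config.temperature * X * nat[None, :]
    grad = -(y - p) @ deta + (theta - mu) / sd**2
    return nlp, grad


def _hessian(theta, w, r, y, config):
    """Analytic Hessian of the negative log posterior at theta."""
    nat = np.exp(theta)
    k = nat[1:]
    eta = config.temperature * (1.0 - w @ nat[1:] - r - nat[0])
    p = expit(eta)
    X = np.column_stack([np.ones_like(r), w])
    deta = -config.temperature * X * nat[None, :]
    H = (p * (1.0 - p) * deta.T) @ deta
    # curvature of eta itself: d2eta/dtheta_j2 = -temp * X_j * nat_j (diagonal)
    H -= np.diag((y - p) @ deta)
    H += np.diag(1.0 / np.asarray(config.prior_sd) ** 2)
    return H


def update_indifference_model(
    history: list[ChoiceObservation],
    config: OTGConfig = OTGConfig(),
    start: IndifferenceModel | None = None,
) -> IndifferenceModel:
    """Refit the indifference curve from the sliding window of recent choices.

    Fewer than ``min_obs`` observations return the prior model unchanged.
    Otherwise the MAP of (b0, k1..k5) is found on the log scale from at most
    the ``window`` most recent observations, always starting from the fixed
    priors (no sequential posterior propagation), and the posterior
    covariance is the inverse curvature at the MAP (Laplace).
    """
    types = {obs.cost_type for obs in history}
    if len(types) > 1:
        raise ValueError(f"observations mix cost types: {sorted(t.value for t in types)}")
    if len(history) < config.min_obs:
        return prior_model(config)
    recent = history[-config.window :]
    r = np.array([o.r for o in recent])
    C = np.array([o.C for o in recent])
    y = np.array([float(o.chose_costly) for o in recent])
    w = _bin_weights(C)

    x0 = start.theta if start is not None else np.asarray(config.prior_loc, dtype=float)
    res = optimize.minimize(
        _neg_log_posterior, x0, args=(w, r, y, config), jac=True,
        method="L-BFGS-B", options={"gtol": config.gtol, "maxiter": 500},
    )
    if not res.success and start is not None:
        # retry from the prior mean if the warm start failed
        res = optimize.minimize(
            _neg_log_posterior, np.asarray(config.prior_loc, dtype=float),
            args=(w, r, y, config), jac=True,
            method="L-BFGS-B", options={"gtol": config.gtol, "maxiter": 500},
        )
    theta = res.x
    H = _hessian(theta, w, r, y, config)
    # guard against non-PD curvature at a boundary-ish optimum
    jitter = 1e-8
    while True:
        try:
            cov = np.linalg.inv(H + jitter * np.eye(len(theta)))
            np.linalg.cholesky(cov)
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > 1.0:
                cov = np.diag(np.asarray(config.prior_sd) ** 2)
                break
    nat = np.exp(theta)
    return IndifferenceModel(
        b0=float(nat[0]), k=nat[1:], fixed_temperature=config.temperature,
        posterior_mean=theta, posterior_cov=cov,
    )


def compute_auc(model: IndifferenceModel, grid: GridSpec | None = None) -> float:
    """Normalised area under the positive part of the indifference curve.

    Trapezoidal integral of max(r*(C), 0) over the cost span [0, 1] (the
    grid costs plus the C -> 0 limit 1 - b0), so a flat curve at r* = 1
    gives 1 and the unit linear curve 1 - C gives exactly 0.5.
    """
    grid = grid or build_grids()
    x = np.concatenate([[0.0], grid.cost_levels])
    y = np.concatenate([[1.0 - model.b0], indifference_reward(grid.cost_levels, model)])
    y = np.clip(y, 0.0, None)
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def fit_indifference_curve_lsq(costs: np.ndarray, rstar: np.ndarray) -> IndifferenceModel:
    """Nonnegative least-squares fit of the 6-parameter curve to target
    indifference rewards (a geometry tool: how flexible is the curve family?)."""
    w = _bin_weights(np.asarray(costs, dtype=float))
    X = np.column_stack([np.ones(len(w)), w])
    res = optimize.lsq_linear(X, 1.0 - np.asarray(rstar, dtype=float), bounds=(0.0, np.inf))
    b0 = max(float(res.x[0]), 1e-12)
    k = np.clip(res.x[1:], 1e-12, None)
    return IndifferenceModel(b0=b0, k=k)


def baseline_sampler(kind: str, n: int, grid: GridSpec, rng: np.random.Generator,
                     cost_type: CostType) -> list[Offer]:
    """Non-adaptive reference designs: a square lattice or uniform random cells.

    GRID requires n in {9, 16, 25, 36, 64} (a square lattice spanning the
    grid extents); RANDOM draws n offers uniformly over the 50 x 50 cells.
    """
    kind = kind.upper()
    if kind == "GRID":
        m = int(round(np.sqrt(n)))
        if m * m != n:
            raise ValueError(f"GRID budget must be a perfect square, got {n}")
        costs = np.linspace(grid.cost_levels[0], grid.cost_levels[-1], m)
        rewards = np.linspace(grid.reward_levels[0], grid.reward_levels[-1], m)
        return [make_offer(cost_type, float(r), float(C)) for C in costs for r in rewards]
    if kind == "RANDOM":
        ci = rng.integers(0, len(grid.cost_levels), size=n)
        ri = rng.integers(0, len(grid.reward_levels), size=n)
        return [
            make_offer(cost_type, float(grid.reward_levels[i]), float(grid.cost_levels[j]))
            for i, j in zip(ri, ci)
        ]
    raise ValueError(f"unknown sampler kind {kind!r}")


class OTGSampler:
    """Closed-loop OTG state: one independently updated indifference model
    per cost type, each probed every fourth trial in the session design.

    Usage: ``offer = s.propose(cost_type, rng)`` then, once the choice is
    observed, ``s.record(offer, chose_costly)``.
    """

    def __init__(self, config: OTGConfig = OTGConfig(), grid: GridSpec | None = None):
        self.config = config
        self.grid = grid or build_grids()
        self.models: dict[CostType, IndifferenceModel] = {t: prior_model(config) for t in CostType}
        self.history: dict[CostType, list[ChoiceObservation]] = {t: [] for t in CostType}
        self._maps: dict[CostType, IndifferenceMap] = {}

    def map_for(self, cost_type: CostType) -> IndifferenceMap:
        if cost_type not in self._maps:
            self._maps[cost_type] = build_indifference_map(self.models[cost_type], self.grid)
        return self._maps[cost_type]

    def propose(self, cost_type: CostType, rng: np.random.Generator) -> Offer:
        return sample_next_offer(self.map_for(cost_type), cost_type, rng)

    def record(self, offer: Offer, chose_costly: bool) -> None:
        t = offer.cost_type
        self.history[t].append(ChoiceObservation(t, offer.r, offer.C, chose_costly))
        self.models[t] = update_indifference_model(
            self.history[t], self.config, start=self.models[t]
        )
        self._maps.pop(t, None)

    def auc(self, cost_type: CostType) -> float:
        return compute_auc(self.models[cost_type], self.grid)

    # --- persistence: a session can be saved and resumed deterministically ---

    def to_json(self) -> str:
        state = {
            "config": {
                "window": self.config.window, "min_obs": self.config.min_obs,
                "temperature": self.config.temperature,
                "prior_loc": list(self.config.prior_loc), "prior_sd": list(self.config.prior_sd),
                "gtol": self.config.gtol,
            },
            "types": {
                t.value: {
                    "b0": self.models[t].b0,
                    "k": self.models[t].k.tolist(),
                    "posterior_mean": self.models[t].posterior_mean.tolist(),
                    "posterior_cov": self.models[t].posterior_cov.tolist(),
                    "history": [
                        [o.r, o.C, int(o.chose_costly)] for o in self.history[t]
                    ],
                }
                for t in CostType
            },
        }
        return json.dumps(state)

    @classmethod
    def from_json(cls, payload: str) -> "OTGSampler":
        state = json.loads(payload)
        cfg = state["config"]
        config = OTGConfig(
            window=cfg["window"], min_obs=cfg["min_obs"], temperature=cfg["temperature"],
            prior_loc=tuple(cfg["prior_loc"]), prior_sd=tuple(cfg["prior_sd"]), gtol=cfg["gtol"],
        )
        sampler = cls(config)
        for t in CostType:
            s = state["types"][t.value]
            sampler.models[t] = IndifferenceModel(
                b0=s["b0"], k=np.array(s["k"]), fixed_temperature=config.temperature,
                posterior_mean=np.array(s["posterior_mean"]),
                posterior_cov=np.array(s["posterior_cov"]),
            )
            sampler.history[t] = [
                ChoiceObservation(t, r, C, bool(y)) for r, C, y in s["history"]
            ]
        return sampler
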