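"""Offline model inversion and random-effects Bayesian model selection.

Fitting follows the statsmodels idiom: build a :class:`ChoiceModel` from a
trial-log DataFrame and a :class:`~moodchoice.choice_models.ModelSpec`, call
``fit()``, and get a :class:`ChoiceModelResults` carrying the MAP estimate,
its Laplace posterior, the log model evidence and per-trial predictions,
with a ``summary()`` table.

Positive parameters (cost weights, reward weight, powers, temperatures) are
estimated on the log scale with Gaussian priors centred at 0 — i.e. centred
at 1 on the natural scale; the bias b0 and the mood weight are Gaussian with
mean 0. The log evidence is a Laplace approximation,

    log E = log p(y | th*) + log p(th*) + d/2 log(2 pi) + 1/2 log det(Cov),

used with the same convention for every model so that only evidence
differences matter in model comparison. Group-level model selection is the
random-effects (Dirichlet) scheme: variational updates of the Dirichlet
posterior over model frequencies, with exceedance probabilities from
Monte-Carlo draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, expit
from statsmodels.tools.numdiff import approx_hess1

from .choice_models import (FIXED_GAMMA, DiscountParams, ModelSpec, MoodVariant, Scheme)
from .core import COST_TYPES, RISK_LOSS_FRAC, CostType

_TYPE_INDEX = {t: i for i, t in enumerate(COST_TYPES)}


@dataclass(frozen=True)
class Priors:
    """Prior scales and centres.

    Positive parameters have Gaussian priors on the log scale with sd
    ``log_sd``; weights and powers are centred at 1. The inverse temperature
    is centred at ``beta1_median`` on the normalised value scale (default
    10, i.e. about 1/3 per euro — the same magnitude as the OTG softmax
    temperature; DV spans about +-1 in these units, so a temperature
    centred at 1 would presume near-random choosers). The bias b0 and the
    mood weight are Gaussian(0, sd) on their natural scale.
    """

    log_sd: float = 1.0
    bias_sd: float = 2.0
    mood_sd: float = 2.0
    beta1_median: float = 10.0


def param_names(spec: ModelSpec) -> list[str]:
    """Canonical free-parameter ordering for a spec."""
    names = []
    if spec.has_reward_weight:
        names.append("k_rew")
    names += [f"k_{t.value}" for t in COST_TYPES]
    if spec.has_power:
        names += [f"gamma_{t.value}" for t in COST_TYPES]
    if spec.temperature_scheme is Scheme.SHARED:
        names.append("beta1")
    elif spec.temperature_scheme is Scheme.SPECIFIC:
        names += [f"beta1_{t.value}" for t in COST_TYPES]
    if spec.bias_scheme is Scheme.SHARED:
        names.append("beta0")
    elif spec.bias_scheme is Scheme.SPECIFIC:
        names += [f"beta0_{t.value}" for t in COST_TYPES]
    if spec.mood_variant is not MoodVariant.NONE:
        names.append("beta_mood")
    return names


def _is_log(name: str) -> bool:
    return not name.startswith(("beta0", "beta_mood"))


def unpack_params(theta: np.ndarray, spec: ModelSpec) -> DiscountParams:
    """Transform a free-parameter vector into an expanded DiscountParams."""
    names = param_names(spec)
    vals = {n: (np.exp(v) if _is_log(n) else float(v)) for n, v in zip(names, theta)}
    p = DiscountParams()
    p.k_rew = vals.get("k_rew", 1.0)
    p.k_cost = {t: vals[f"k_{t.value}"] for t in COST_TYPES}
    p.gamma = (
        {t: vals[f"gamma_{t.value}"] for t in COST_TYPES} if spec.has_power else dict(FIXED_GAMMA)
    )
    if spec.temperature_scheme is Scheme.SPECIFIC:
        p.beta1 = {t: vals[f"beta1_{t.value}"] for t in COST_TYPES}
    elif spec.temperature_scheme is Scheme.SHARED:
        p.beta1 = {t: vals["beta1"] for t in COST_TYPES}
    else:
        p.beta1 = {t: 1.0 for t in COST_TYPES}
    if spec.bias_scheme is Scheme.SPECIFIC:
        p.beta0 = {t: vals[f"beta0_{t.value}"] for t in COST_TYPES}
    elif spec.bias_scheme is Scheme.SHARED:
        p.beta0 = {t: vals["beta0"] for t in COST_TYPES}
    else:
        p.beta0 = {t: 0.0 for t in COST_TYPES}
    p.beta_mood = vals.get("beta_mood", 0.0)
    return p


def pack_params(params: DiscountParams, spec: ModelSpec) -> np.ndarray:
    """Inverse of :func:`unpack_params` (shared schemes read the risk entry)."""
    out = []
    for n in param_names(spec):
        if n == "k_rew":
            v = params.k_rew
        elif n == "beta_mood":
            v = params.beta_mood
        elif n in ("beta1", "beta0"):
            d = params.beta1 if n == "beta1" else params.beta0
            v = d[COST_TYPES[0]]
        else:
            prefix, tname = n.split("_", 1)
            t = CostType(tname)
            v = {"k": params.k_cost, "gamma": params.gamma, "beta1": params.beta1, "beta0": params.beta0}[prefix][t]
        out.append(np.log(v) if _is_log(n) else v)
    return np.array(out)


class ChoiceModel:
    """MAP/Laplace inversion of one discount/softmax model on one subject's trials.

    Parameters
    ----------
    trials : DataFrame
        One row per choice with columns ``cost_type`` (label or CostType),
        ``r``, ``C``, ``choice`` (1 = costly) and, for mood variants,
        ``mood_z``.
    spec : ModelSpec
    priors : Priors, optional
    """

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec, priors: Priors = Priors()):
        if len(trials) == 0:
            raise ValueError("no trials to fit")
        self.spec = spec
        self.priors = priors
        self.trials = trials
        ct = trials["cost_type"].map(lambda v: v if isinstance(v, CostType) else CostType(str(v)))
        self.t_idx = ct.map(_TYPE_INDEX).to_numpy()
        self.r = trials["r"].to_numpy(dtype=float)
        self.C = trials["C"].to_numpy(dtype=float)
        self.loss = np.where(self.t_idx == _TYPE_INDEX[CostType.RISK], RISK_LOSS_FRAC, 0.0)
        self.endog = trials["choice"].to_numpy(dtype=float)
        if spec.mood_variant is not MoodVariant.NONE:
            if "mood_z" not in trials:
                raise ValueError("mood variants require a mood_z column")
            self.mood = trials["mood_z"].to_numpy(dtype=float)
        else:
            self.mood = np.zeros(len(trials))
        self.names = param_names(spec)
        self._is_log = np.array([_is_log(n) for n in self.names])
        self._prior_sd = np.array(
            [priors.log_sd if _is_log(n) else (priors.mood_sd if n == "beta_mood" else priors.bias_sd)
             for n in self.names]
        )
        self._prior_loc = np.array(
            [np.log(priors.beta1_median) if n.startswith("beta1") else 0.0 for n in self.names]
        )
        self._masks = [self.t_idx == i for i in range(4)]

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, spec: ModelSpec, priors: Priors = Priors()):
        return cls(trials, spec, priors)

    # --- likelihood machinery -------------------------------------------------

    def _expand(self, theta: np.ndarray):
        """Per-trial natural-scale parameter arrays from the free vector."""
        names = self.names
        vals = dict(zip(names, theta))
        get = lambda n, d: np.exp(vals[n]) if n in vals else d
        k_rew = get("k_rew", 1.0)
        kc = np.empty(4)
        gam = np.empty(4)
        b1 = np.empty(4)
        b0 = np.empty(4)
        for i, t in enumerate(COST_TYPES):
            kc[i] = np.exp(vals[f"k_{t.value}"])
            gam[i] = np.exp(vals[f"gamma_{t.value}"]) if self.spec.has_power else FIXED_GAMMA[t]
            if self.spec.temperature_scheme is Scheme.SPECIFIC:
                b1[i] = np.exp(vals[f"beta1_{t.value}"])
            elif self.spec.temperature_scheme is Scheme.SHARED:
                b1[i] = np.exp(vals["beta1"])
            else:
                b1[i] = 1.0
            if self.spec.bias_scheme is Scheme.SPECIFIC:
                b0[i] = vals[f"beta0_{t.value}"]
            elif self.spec.bias_scheme is Scheme.SHARED:
                b0[i] = vals["beta0"]
            else:
                b0[i] = 0.0
        bm = vals.get("beta_mood", 0.0)
        return k_rew, kc, gam, b1, b0, bm

    def predict_p(self, theta: np.ndarray) -> np.ndarray:
        """P(costly) per trial at a free-parameter vector."""
        k_rew, kc, gam, b1, b0, bm = self._expand(theta)
        ti = self.t_idx
        kct, gamt = kc[ti], gam[ti]
        b1t, b0t = b1[ti], b0[ti]
        if self.spec.mood_variant is MoodVariant.MULTIPLICATIVE:
            krew_t = k_rew * (1.0 + bm * self.mood)
        else:
            krew_t = np.full(len(ti), k_rew)
        v = np.empty(len(ti))
        m_risk, m_delay = self._masks[0], self._masks[1]
        m_eff = ~(m_risk | m_delay)
        v[m_risk] = (
            krew_t[m_risk] * (1.0 - self.C[m_risk])
            - kct[m_risk] * self.loss[m_risk] * self.C[m_risk] ** gamt[m_risk]
        )
        v[m_delay] = krew_t[m_delay] * np.exp(-kct[m_delay] * self.C[m_delay] ** gamt[m_delay])
        v[m_eff] = krew_t[m_eff] - kct[m_eff] * self.C[m_eff] ** gamt[m_eff]
        dv = v - krew_t * self.r
        if self.spec.mood_variant is MoodVariant.ADDITIVE:
            b0t = b0t * (1.0 + bm * self.mood)
        return expit(b0t + b1t * dv)

    def _neg_log_posterior(self, theta: np.ndarray) -> float:
        p = self.predict_p(theta)
        eps = 1e-12
        nll = -np.sum(self.endog * np.log(p + eps) + (1.0 - self.endog) * np.log(1.0 - p + eps))
        return float(nll + 0.5 * np.sum(((theta - self._prior_loc) / self._prior_sd) ** 2))

    def log_prior(self, theta: np.ndarray) -> float:
        sd = self._prior_sd
        z = (theta - self._prior_loc) / sd
        return float(-0.5 * np.sum(z**2) - np.sum(np.log(sd)) - 0.5 * len(sd) * np.log(2 * np.pi))

    # --- fitting --------------------------------------------------------------

    def fit(self, n_restarts: int = 5, seed: int = 0, maxiter: int = 1000) -> "ChoiceModelResults":
        """Multi-start MAP optimisation followed by a Laplace approximation."""
        for i, mask in enumerate(self._masks):
            # a cost type with no trials leaves its weight (and any specific
            # softmax parameters) pinned to the prior
            if not mask.any():
                warnings.warn(f"no trials for {COST_TYPES[i].value}; its parameters follow the prior")
        rng = np.random.default_rng(seed)
        d = len(self.names)
        starts = [self._prior_loc.copy()]
        starts += [self._prior_loc + 0.5 * self._prior_sd * rng.standard_normal(d)
                   for _ in range(n_restarts - 1)]
        best = None
        any_success = False
        for x0 in starts:
            res = optimize.minimize(
                self._neg_log_posterior, x0, method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": 1e-6},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if not any_success:
            warnings.warn("MAP optimisation did not converge; returning best iterate")
        theta = best.x
        H = approx_hess1(theta, self._neg_log_posterior)
        H = 0.5 * (H + H.T)
        jitter = 1e-8
        while True:
            try:
                cov = np.linalg.inv(H + jitter * np.eye(d))
                np.linalg.cholesky(cov)
                break
            except np.linalg.LinAlgError:
                jitter *= 10.0
                if jitter > 1e3:
                    cov = np.diag(self._prior_sd**2)
                    break
        p_hat = self.predict_p(theta)
        eps = 1e-12
        loglik = float(np.sum(self.endog * np.log(p_hat + eps) + (1 - self.endog) * np.log(1 - p_hat + eps)))
        sign, logdet = np.linalg.slogdet(cov)
        log_evidence = loglik + self.log_prior(theta) + 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet
        return ChoiceModelResults(
            model=self, spec=self.spec, theta_map=theta, posterior_cov=cov,
            log_evidence=float(log_evidence), loglik=loglik, predicted_p=p_hat,
            converged=any_success,
        )


@dataclass
class ChoiceModelResults:
    """MAP estimate, Laplace posterior and evidence for one fitted model."""

    model: ChoiceModel
    spec: ModelSpec
    theta_map: np.ndarray  # free vector, log scale for positive parameters
    posterior_cov: np.ndarray
    log_evidence: float
    loglik: float
    predicted_p: np.ndarray
    converged: bool

    def __post_init__(self):
        if (
            self.spec.mood_variant is MoodVariant.ADDITIVE
            and np.all(np.abs(self._beta0_values()) < 1e-3)
        ):
            warnings.warn(
                "fitted |beta0| < 1e-3: the additive mood modulation "
                "beta0*(1+beta_mood*mood) has no lever and beta_mood is unidentified"
            )

    def _beta0_values(self) -> np.ndarray:
        p = self.params
        return np.array([p.beta0[t] for t in COST_TYPES])

    @property
    def names(self) -> list[str]:
        return self.model.names

    @property
    def params(self) -> DiscountParams:
        """Natural-scale MAP parameters."""
        return unpack_params(self.theta_map, self.spec)

    @property
    def posterior_variance(self) -> np.ndarray:
        """Marginal posterior variances on the estimation (log/linear) scale."""
        return np.diag(self.posterior_cov)

    def params_natural(self) -> pd.Series:
        vals = [np.exp(v) if _is_log(n) else v for n, v in zip(self.names, self.theta_map)]
        return pd.Series(vals, index=self.names)

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        """Natural-scale equal-tailed intervals from the Gaussian posterior."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        sd = np.sqrt(self.posterior_variance)
        lo, hi = self.theta_map - z * sd, self.theta_map + z * sd
        rows = []
        for n, a, b in zip(self.names, lo, hi):
            if _is_log(n):
                a, b = np.exp(a), np.exp(b)
            rows.append((n, a, b))
        return pd.DataFrame(rows, columns=["parameter", "lower", "upper"]).set_index("parameter")

    def balanced_accuracy(self) -> float:
        return balanced_accuracy(self.predicted_p, self.model.endog)

    def summary(self) -> str:
        ci = self.credible_interval()
        nat = self.params_natural()
        sd = np.sqrt(self.posterior_variance)
        lines = [
            "Discount/softmax choice model (MAP + Laplace)",
            f"  spec: {self.spec.code}   free parameters: {self.spec.n_free_params}",
            f"  trials: {len(self.model.endog)}   log evidence: {self.log_evidence:.2f}"
            f"   log lik: {self.loglik:.2f}   converged: {self.converged}",
            "",
            f"  {'parameter':<22}{'estimate':>10}{'post sd*':>10}{'95% lo':>10}{'95% hi':>10}",
        ]
        for i, n in enumerate(self.names):
            lines.append(
                f"  {n:<22}{nat[n]:>10.3f}{sd[i]:>10.3f}"
                f"{ci.loc[n, 'lower']:>10.3f}{ci.loc[n, 'upper']:>10.3f}"
            )
        lines.append("  * posterior sd on the estimation scale (log for positive parameters)")
        return "\n".join(lines)


def fit_choice_model(trials: pd.DataFrame, spec: ModelSpec, priors: Priors = Priors(),
                     n_restarts: int = 5, seed: int = 0) -> ChoiceModelResults:
    """Functional wrapper: ``ChoiceModel(trials, spec, priors).fit()``."""
    return ChoiceModel(trials, spec, priors).fit(n_restarts=n_restarts, seed=seed)


# --- group-level random-effects model selection -------------------------------


@dataclass(frozen=True)
class BMSResult:
    """Posterior over model frequencies in the population."""

    alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    model_labels: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        labels = self.model_labels or [f"m{i}" for i in range(len(self.alpha))]
        return pd.DataFrame(
            {
                "model": labels,
                "alpha": self.alpha,
                "expected_frequency": self.expected_frequencies,
                "exceedance_probability": self.exceedance_probabilities,
            }
        )


def bms(log_evidence: np.ndarray, n_mc: int = 100_000, tol: float = 1e-6,
        max_iter: int = 10_000, seed: int = 0,
        model_labels: tuple[str, ...] = ()) -> BMSResult:
    """Random-effects Bayesian model selection over a subjects x models
    log-evidence matrix (variational Dirichlet scheme).

    Expected frequencies are the Dirichlet mean; exceedance probabilities —
    the probability that each model is the most frequent — come from
    Monte-Carlo draws of the Dirichlet posterior.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 2:
        raise ValueError("need a (subjects x models) matrix with >= 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    n, K = L.shape
    L = L - L.max(axis=1, keepdims=True)
    alpha0 = np.ones(K)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(logu - logu.max(axis=1, keepdims=True))
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_mc
    return BMSResult(
        alpha=alpha, expected_frequencies=alpha / alpha.sum(),
        exceedance_probabilities=ep, model_labels=tuple(model_labels),
    )


def balanced_accuracy(predicted_p: np.ndarray, choices: np.ndarray) -> float:
    """Mean of per-class predictive accuracies (threshold 0.5)."""
    p = np.asarray(predicted_p, dtype=float)
    y = np.asarray(choices, dtype=float)
    if len(p) != len(y):
        raise ValueError("length mismatch")
    pred = p >= 0.5
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy requires both choice classes")
    return float(0.5 * (np.mean(pred[pos]) + np.mean(~pred[neg])))


@dataclass
class RecoveryReport:
    """Per-sampler simulation metrics for design comparison."""

    sampler: str
    n_trials: int
    n_simulations: int
    balanced_accuracy: float
    mean_posterior_variance: float
    recovery_correlation: pd.Series
    degenerate_params: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sampler": self.sampler,
            "n_trials": self.n_trials,
            "n_simulations": self.n_simulations,
            "balanced_accuracy": self.balanced_accuracy,
            "mean_posterior_variance": self.mean_posterior_variance,
            **{f"corr_{k}": v for k, v in self.recovery_correlation.items()},
        }


def recovery_metrics(simulated_params: np.ndarray, fit_results: list[ChoiceModelResults],
                     sampler: str = "", n_trials: int = 0,
                     balanced_accuracies: list[float] | None = None) -> RecoveryReport:
    """Simulated-vs-fitted Pearson correlations per parameter, plus mean
    balanced accuracy and mean posterior variance across simulations.

    ``simulated_params`` rows align with ``fit_results``; columns follow the
    fitted spec's :func:`param_names` order, on the natural scale. By default
    balanced accuracy is each fit's accuracy on its own trials; pass
    ``balanced_accuracies`` to use externally evaluated scores (e.g. on a
    common evaluation set shared by all samplers).
    """
    sims = np.asarray(simulated_params, dtype=float)
    if len(fit_results) != sims.shape[0]:
        raise ValueError("simulated_params rows must align with fit_results")
    if len(fit_results) < 3:
        raise ValueError("need >= 3 simulations for recovery correlations")
    names = fit_results[0].names
    fitted = np.vstack([r.params_natural().to_numpy() for r in fit_results])
    corrs, degenerate = [], []
    for j, n in enumerate(names):
        a, b = sims[:, j], fitted[:, j]
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            corrs.append(0.0)
            degenerate.append(n)
        else:
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
    if balanced_accuracies is None:
        ba = float(np.mean([r.balanced_accuracy() for r in fit_results]))
    else:
        if len(balanced_accuracies) != len(fit_results):
            raise ValueError("balanced_accuracies must align with fit_results")
        ba = float(np.mean(balanced_accuracies))
    mpv = float(np.mean([np.mean(r.posterior_variance) for r in fit_results]))
    return RecoveryReport(
        sampler=sampler, n_trials=n_trials, n_simulations=len(fit_results),
        balanced_accuracy=ba, mean_posterior_variance=mpv,
        recovery_correlation=pd.Series(corrs, index=names),
        degenerate_params=tuple(degenerate),
    )
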