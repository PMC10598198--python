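# Methods

`moodchoice` implements a closed-loop experimental-design algorithm —
online trial generation (OTG) — for probing cost–benefit indifference
points, together with the family of discount/softmax choice models used to
analyse the resulting choices, a mood-modulated choice bias, Bayesian model
inversion and random-effects model selection, and a synthetic-data
generator that reproduces the statistical structure of the mood-induction
experiment the analyses assume. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Units and scales

Everything is computed in normalised units: the large reward is 1
(30 € at display scale), small rewards `r ∈ (0,1)` are fractions of it, and
each cost `C ∈ (0,1]` is a fraction of its type maximum — a 100% chance of
losing 10 € (risk), one year of delay, 12 flights of stairs (physical
effort), or 12 pages of 25 lines to copy (mental effort; the 12-page
maximum is set by symmetry with the 12 flights and is configurable).
Euro/day/flight/line scales appear only in `offer_to_physical` and its
inverse, which round-trip within grid resolution.

One consequence deserves emphasis: softmax inverse temperatures are
scale-dependent. Decision values span roughly ±1 in normalised units
(±30 in euros), so a temperature of 1 per euro corresponds to ≈30 on our
scale, and a temperature of 1 on our scale describes a near-random chooser.
Throughout the package the canonical "realistic" choice consistency is an
inverse temperature of order 10 on the normalised scale (≈1/3 per euro):
it is the default fixed temperature of the OTG likelihood, the median of
the synthetic population's `β1`, and the centre of the fitting prior for
`β1`. Using a single magnitude for all three keeps the generator, the
adaptive sampler and the fitter mutually coherent.

## Choice models

Subjective value of the costly option, per cost type (Rew = 1):

* risk: `V = k_Rew·Rew·P − k_R·L·(1−P)^γ_R`, with win probability
  `P = 1 − C` and stake `L = 1/3`;
* delay: `V = k_Rew·Rew·exp(−k_D·D^γ_D)` (always positive);
* efforts: `V = k_Rew·Rew − k_E·E^γ_E` (can go negative, like risk).

The uncostly option is worth `k_Rew·r`. Choices follow
`P(costly) = σ(β0 + β1·DV)` with `DV = V(costly) − V(uncostly)`. The model
space crosses reward weight (on/off) × cost powers (free / fixed at 1, 1,
2, 2) × `β1` scheme × `β0` scheme (each absent / shared / cost-specific),
36 candidates in all; an absent temperature means `β1 ≡ 1` (a softmax needs
some temperature; fixing it at 1 is the only parameter-free reading) and an
absent bias means `β0 ≡ 0`. The reference ("winning") model has a shared
reward weight, fixed powers and cost-specific `β1`, `β0` — 13 free
parameters. When the powers are free they are cost-specific but toggled as
one factor, which is what makes the 2×2×3×3 space count 36.

Mood enters in one of two ways: additively on the bias,
`P(costly) = σ(β0·(1 + β_mood·m) + β1·DV)`, or multiplicatively on the
reward weight, `k_Rew·(1 + β_mood·m)`. `m` is the trial's mood rating
z-scored per session (the rating scale itself is arbitrary; z-scoring is
also what the analyses use). Note the additive form has no lever when
`β0 = 0`; the fitter warns when all fitted `|β0| < 1e−3` because `β_mood`
is then unidentified.

## Online trial generation

The indifference curve `r*(C)` is modelled agnostically as five
edge-constrained linear pieces over the cost bins `(0,.2], …, (.8,1]`, with
an uncostly-bonus intercept `b0`: in bin j,
`r*(C) = 1 − b0 − Σ_{i<j} k_i·0.2 − k_j·(C − 0.2(j−1))`. Six parameters in
total; nonnegative least squares shows the family tracks exponential
(`e^{−2C}`) and parabolic (`1 − C²`) discounting to within 0.05 on the
50-level cost grid, which is the sense in which it commits to no
discounting shape.

After every choice, the parameters of the current cost type are refitted
by MAP from a sliding window of the 20 most recent choices of that type
(updates start after the third choice; each cost type is probed every
fourth trial and keeps an independent model). The likelihood is a softmax
of `r*(C) − r` at a *fixed* temperature (default 10, configurable; it is
deliberately not a free parameter — six parameters on ≤20 observations is
already generous). Positivity is enforced by fitting `log(b0, k1..k5)` with
Gaussian priors: slopes centred at 1 (log 0, sd 1), `b0` centred just
above 0 (log-scale mean −3, sd 1). Each refit restarts from the priors
rather than propagating a posterior — the window, not the posterior,
carries memory, which is what lets preferences drift with mood or time.
The posterior covariance is the inverse curvature at the MAP (Laplace),
with an analytic gradient and Hessian. Optimiser: L-BFGS-B, gradient
tolerance 1e−6, warm-started from the previous fit with a prior-mean
restart on failure.

The indifference map scores each of the 50×50 (reward × cost) grid cells
by `(0.5 − |p − 0.5|)/0.5`; column sums, normalised, give the sampling
density over cost levels. The next offer draws a cost from that density and
pairs it with the grid reward closest to `r*(C)` (clipped into range, ties
toward the lower reward). AUC — the continuous willingness-to-accept-costs
index — is the trapezoidal integral of `max(r*(C), 0)` over `{0} ∪ grid`
(so the flat curve `r* ≡ 1` gives 1 and the unit linear curve `1 − C`
gives exactly 0.5). Baseline samplers for comparison: a √n×√n lattice
spanning the grid extents (n ∈ {9, 16, 25, 36, 64}) and uniform random
cells. OTG state serialises to JSON so a session can be resumed.

## Inversion and model selection

`ChoiceModel.fit()` performs multi-start MAP (5 seeded restarts, best
posterior kept) on the free-parameter vector — positive parameters on the
log scale with priors `N(0, 1)` (centred at 1 naturally; `β1` centred at
10, see Units), `β0` and `β_mood` with `N(0, 2)` — followed by a Laplace
approximation:
`log E = log lik + log prior + d/2·log 2π + ½·log det Σ`. The convention is
applied identically to every model, so only evidence differences matter.
This replaces the variational inversion used in the original analyses; any
consistent evidence approximation supports the same comparisons, and the
suite checks the Occam property directly (bias-free data favour the
bias-free model on average).

Group-level selection is random-effects BMS: variational updates of a
Dirichlet posterior over model frequencies (tolerance 1e−6), exceedance
probabilities from 1e5 Dirichlet draws. Protected exceedance probabilities
and hierarchical priors are out of scope.

In the sampler-comparison driver, balanced accuracy — the mean of per-class
accuracies at threshold 0.5 — is evaluated on the *pooled* trials of all
samplers at a budget (the same simulated agent answers every sampler's
option pairs, so these form one common choice sequence). Evaluated on each
sampler's own trials the score would reward designs that generate easy,
far-from-indifference trials rather than good estimates. Posterior variance
and simulated-vs-fitted correlations are per fit.

## Synthetic data

A session is 128 trials: two positive and two negative 18-trial episodes in
random order, each flanked by its own 7-trial transition block. Quiz
correctness is Bernoulli with condition-dependent difficulty (0.506 /
0.358 / 0.216 for positive / transition / negative); correct answers always
earn positive feedback and errors are converted to positive feedback with
probability 0.50 / 0.25 / 0, so expected positive-feedback rates are
≈76 / 52 / 22%. Cost types occupy consecutive blocks of four (one each,
rejection-resampled so no type repeats across block boundaries); transition
blocks are not shared between adjacent episodes (4×18 + 8×7 = 128). Episode
order is randomised independently per session.

Mood is generated by a leaky integrator,
`m_t = λ·m_{t−1} + w⁺·[pos] − w⁻·[neg] + ε_t`, defaults λ = 0.85,
w⁺ = 0.05, w⁻ = 0.09, ε-sd = 0.03 on a nominal [−1, 1] scale — the
experiment only *measures* mood, so this generator is a modelling choice,
calibrated so that within-episode slopes are a few hundredths of a z-unit
per trial with negative induction stronger than positive, and mood returns
toward baseline during transitions. Because feedback and mood do not depend
on the economic choices, sessions are simulated in two passes: feedback and
mood first (fixing the per-session z-scored mood that the additive bias
uses — matching analysis-time z-scoring), then the closed offer–choice
loop. OTG state is fresh per session (no multi-session pooling).

Agents draw scale-free positive parameters log-normally (median 1, log-sd
0.5), `β1` log-normally with median 10 (see Units), `β0 ~ N(0, 1)` and
`β_mood ~ N(0.6, 1.75)` — the mean is the reported group-level mood bias
and the spread follows from its t-statistic (SE 0.173 × √102). Optional
flags fold `β0` and/or `β_mood` positive, for cohorts whose mood lever must
not flip sign across agents (the end-to-end analyses construct their
effects through `β0·β_mood > 0`). The RT generator,
`rt = max(base − slope·e, floor)·lognormal`, shortens responses as the
bias-inclusive evidence `e` toward the chosen option grows; it exists to
exercise the RT analyses (filtering, residualisation, the choice ×
condition interaction, which is negative under +1 = costly / +1 = positive
coding) and makes no mechanistic claim.

## Analyses

`preprocess_rt` keeps 0.75 s < RT < 10 s and within median ± 3 SD per
subject, z-scores, and residualises session and within-session trial
number. `analyze_mood_effects` computes, per subject, the costly-choice
contrast between positive and negative episodes (pooled and per cost
type), a logistic regression of choice on z-scored mood, the RT
choice × condition regression on the preprocessed residuals, and
within-episode slopes of the AUC trace (z-scored per session, each cost
type's stepwise trace linearly interpolated onto all trials and averaged,
with the linear time-on-task trend removed); group inference is two-tailed
one-sample t-tests on the per-subject statistics, reported without
multiple-testing correction alongside the α used.

## Problem sizes and numerical choices

Full-scale sampler comparisons use a simulation budget equal to the cube of
the free-parameter count (13³ = 2197; 14³ = 2744 with the mood weight). The
shipped tests run scaled versions chosen as adequate for their qualitative
claims: 100 simulations × 256 trials for mood-weight recoverability and the
OTG-vs-random contrasts, 20-subject cohorts for model recovery and
mood-mechanism arbitration, 30-agent (effect) and 10 × 12-agent (null
calibration) cohorts for the end-to-end battery. Optimisation details:
L-BFGS-B throughout, numerical Hessians (statsmodels `approx_hess1`) for
the choice-model Laplace step with symmetrisation and jitter escalation if
the curvature is not positive definite; fits that fail to converge warn and
return the best iterate; driver-level failures are flagged rows, never
silent drops.

## Known limitations

* The recovery of individual piecewise-curve slopes is limited by choice
  noise: at the default OTG temperature, ~200 choices pin down the curve
  `r*(C)` to within ~0.1 but individual bin slopes trade off against each
  other. The option-selection step only needs the curve.
* Evidence-based selection among nested softmax variants (shared vs
  cost-specific `β1`/`β0`) is weakly powered at 256 trials per subject when
  the population's between-type heterogeneity is modest: the simpler model
  is then often — correctly, in Occam terms — preferred.
* The mood generator and RT generator are conveniences with the right
  qualitative structure (episode slopes, asymmetry, RT–value coupling);
  passing tests show the pipeline detects effects of the constructed form,
  not that real mood dynamics follow a leaky integrator.
* The synthetic population is log-normal/Gaussian by construction; real
  parameter distributions are heavier-tailed and correlated across
  parameters.
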