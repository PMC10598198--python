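"""The online-trial-generation machinery: indifference curve, map, sampling,
sliding-window Bayesian updates, AUC, and baseline designs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import moodchoice as mc
from moodchoice.core import CostType
from moodchoice.otg import (ChoiceObservation, OTGConfig, OTGSampler,
                            baseline_sampler, fit_indifference_curve_lsq,
                            prior_model, update_indifference_model)

params_strategy = st.tuples(
    st.floats(0.0, 0.3),  # b0
    st.lists(st.floats(0.05, 4.0), min_size=5, max_size=5),
)


class TestIndifferenceCurve:
    def test_linear_curve(self, linear_model):
        assert mc.indifference_reward(0.5, linear_model) == pytest.approx(0.5)

    def test_intercept_and_first_slope(self):
        m = mc.IndifferenceModel(b0=0.1, k=np.array([2.0, 1, 1, 1, 1]))
        assert mc.indifference_reward(0.1, m) == pytest.approx(0.7)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(params=params_strategy, j=st.integers(1, 4))
    def test_continuity_at_bin_edges(self, params, j):
        b0, k = params
        m = mc.IndifferenceModel(b0=b0, k=np.array(k))
        edge = 0.2 * j
        left = mc.indifference_reward(edge - 1e-9, m)
        right = mc.indifference_reward(edge + 1e-9, m)
        assert right == pytest.approx(left, abs=1e-6)

    def test_rejects_out_of_range(self, linear_model):
        for C in (0.0, -0.1, 1.01):
            with pytest.raises(ValueError):
                mc.indifference_reward(C, linear_model)

    @pytest.mark.parametrize(
        "target_fn",
        [lambda C: np.exp(-2 * C), lambda C: 1 - C**2],
        ids=["exponential-decay", "parabolic-decay"],
    )
    def test_flexibility_approximates_discounting_shapes(self, grid, target_fn):
        """Five edge-constrained linear pieces track convex and concave
        discounting to within 0.05 everywhere on the cost grid."""
        target = target_fn(grid.cost_levels)
        model = fit_indifference_curve_lsq(grid.cost_levels, target)
        fitted = mc.indifference_reward(grid.cost_levels, model)
        assert np.max(np.abs(fitted - target)) < 0.05


class TestIndifferenceScore:
    @pytest.mark.parametrize("p,score", [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.75, 0.5)])
    def test_values(self, p, score):
        assert mc.indifference_score(p) == pytest.approx(score)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 1.0))
    def test_normalised_and_symmetric(self, p):
        s = mc.indifference_score(p)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(mc.indifference_score(1.0 - p), abs=1e-12)

    def test_rejects_outside_unit_interval(self):
        with pytest.raises(ValueError):
            mc.indifference_score(1.2)


class TestIndifferenceMap:
    def test_argmax_reward_tracks_rstar(self, grid, linear_model):
        imap = mc.build_indifference_map(linear_model, grid)
        for j in [0, 10, 25, 40]:
            best = grid.reward_levels[np.argmax(imap.scores[:, j])]
            assert best == pytest.approx(grid.nearest_reward(imap.rstar[j]))

    def test_density_normalises(self, grid):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = mc.IndifferenceModel(b0=rng.uniform(0, 0.3), k=rng.uniform(0.1, 3.0, 5))
            imap = mc.build_indifference_map(m, grid)
            assert imap.cost_density.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(imap.cost_density >= 0)
            assert np.all((imap.scores >= 0) & (imap.scores <= 1))

    def test_flat_scores_give_uniform_density(self, grid, linear_model):
        m = mc.IndifferenceModel(b0=0.0, k=np.ones(5), fixed_temperature=1e-9)
        imap = mc.build_indifference_map(m, grid)
        np.testing.assert_allclose(imap.cost_density, 1 / 50, atol=1e-9)

    def test_linear_model_mass_near_antidiagonal(self, grid, linear_model):
        """Columns whose indifference point lies on-grid outscore the ones
        where the curve exits the reward range."""
        imap = mc.build_indifference_map(linear_model, grid)
        interior = imap.cost_density[5:45].mean()
        assert interior > 1 / 50 * 0.9


class TestSampleNextOffer:
    def test_point_mass_density(self, grid, linear_model):
        imap = mc.build_indifference_map(linear_model, grid)
        dens = np.zeros(50)
        j_star = 24
        dens[j_star] = 1.0
        forced = mc.IndifferenceMap(grid=grid, scores=imap.scores, cost_density=dens,
                                    rstar=imap.rstar)
        rng = np.random.default_rng(0)
        for _ in range(10):
            offer = mc.sample_next_offer(forced, CostType.DELAY, rng)
            assert offer.C == pytest.approx(grid.cost_levels[j_star])

    def test_reward_within_one_grid_step_of_indifference(self, grid, linear_model):
        imap = mc.build_indifference_map(linear_model, grid)
        rng = np.random.default_rng(1)
        step = grid.reward_levels[1] - grid.reward_levels[0]
        for _ in range(200):
            offer = mc.sample_next_offer(imap, CostType.RISK, rng)
            assert abs(offer.r - (1.0 - offer.C)) <= step / 2 + 1e-9
            assert offer.r in grid.reward_levels
            assert offer.C in grid.cost_levels

    def test_empirical_frequencies_match_density(self, grid, linear_model):
        imap = mc.build_indifference_map(linear_model, grid)
        rng = np.random.default_rng(2)
        n = 10_000
        counts = np.zeros(50)
        for _ in range(n):
            offer = mc.sample_next_offer(imap, CostType.DELAY, rng)
            counts[grid.nearest_cost_index(offer.C)] += 1
        freq = counts / n
        se = np.sqrt(imap.cost_density * (1 - imap.cost_density) / n)
        assert np.all(np.abs(freq - imap.cost_density) <= 3.5 * se + 1e-4)


class TestUpdate:
    def test_fewer_than_three_returns_prior(self):
        cfg = OTGConfig()
        obs = [ChoiceObservation(CostType.RISK, 0.5, 0.5, True)] * 2
        m = update_indifference_model(obs, cfg)
        p = prior_model(cfg)
        np.testing.assert_array_equal(m.posterior_mean, p.posterior_mean)
        np.testing.assert_array_equal(m.posterior_cov, p.posterior_cov)

    def test_sliding_window_ignores_old_observations(self, rng):
        cfg = OTGConfig()
        obs = [
            ChoiceObservation(CostType.DELAY, float(r), float(C), bool(y))
            for r, C, y in zip(rng.uniform(0.1, 0.9, 22), rng.uniform(0.05, 1.0, 22),
                               rng.integers(0, 2, 22))
        ]
        perturbed = list(obs)
        perturbed[0] = ChoiceObservation(CostType.DELAY, 0.99, 0.01, True)
        a = update_indifference_model(obs, cfg)
        b = update_indifference_model(perturbed, cfg)
        np.testing.assert_allclose(a.posterior_mean, b.posterior_mean)

    def test_mixed_cost_types_rejected(self):
        obs = [
            ChoiceObservation(CostType.RISK, 0.5, 0.5, True),
            ChoiceObservation(CostType.DELAY, 0.5, 0.5, True),
            ChoiceObservation(CostType.RISK, 0.5, 0.5, False),
        ]
        with pytest.raises(ValueError, match="mix"):
            update_indifference_model(obs, OTGConfig())

    @staticmethod
    def _closed_loop_fit(grid, temperature, seed, n_trials=200):
        rng = np.random.default_rng(seed)
        cfg = OTGConfig(window=300, temperature=temperature)
        sampler = OTGSampler(cfg, grid)
        for _ in range(n_trials):
            offer = sampler.propose(CostType.DELAY, rng)
            p = 1.0 / (1.0 + np.exp(-temperature * ((1 - offer.C) - offer.r)))
            sampler.record(offer, bool(rng.random() < p))
        return sampler.models[CostType.DELAY]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_curve_recovery_linear_agent(self, grid, seed):
        """200 closed-loop choices from an agent with true curve r* = 1 - C
        recover the curve itself to within 0.1 everywhere (individual bin
        slopes trade off against each other under choice noise, but the
        curve — what the option selection uses — is identified)."""
        m = self._closed_loop_fit(grid, temperature=10.0, seed=seed)
        fitted = mc.indifference_reward(grid.cost_levels, m)
        assert np.max(np.abs(fitted - (1 - grid.cost_levels))) < 0.1

    def test_slope_recovery_high_consistency_agent(self, grid):
        """With nearly deterministic choices the individual slopes and the
        bonus are themselves pinned down."""
        m = self._closed_loop_fit(grid, temperature=50.0, seed=0)
        assert np.all(np.abs(m.k - 1.0) < 0.15)
        assert abs(m.b0) < 0.1

    def test_closed_loop_concentrates_near_true_indifference(self, grid):
        """Presented rewards approach the agent's true indifference curve."""
        rng = np.random.default_rng(8)
        sampler = OTGSampler(OTGConfig(), grid)
        errs = []
        for _ in range(120):
            offer = sampler.propose(CostType.DELAY, rng)
            p = 1.0 / (1.0 + np.exp(-10.0 * ((1 - offer.C) - offer.r)))
            sampler.record(offer, bool(rng.random() < p))
            errs.append(abs(offer.r - (1 - offer.C)))
        assert np.median(errs[-30:]) < np.median(errs[:30])


class TestAUC:
    def test_unit_linear_curve_exactly_half(self, linear_model):
        assert mc.compute_auc(linear_model) == pytest.approx(0.5)

    def test_flat_curve_tends_to_one(self):
        m = mc.IndifferenceModel(b0=0.0, k=np.full(5, 1e-9))
        assert mc.compute_auc(m) == pytest.approx(1.0, abs=1e-6)

    def test_decreasing_in_each_slope(self):
        base = mc.IndifferenceModel(b0=0.05, k=np.full(5, 0.5))
        auc0 = mc.compute_auc(base)
        for i in range(5):
            k = np.full(5, 0.5)
            k[i] = 0.8
            assert mc.compute_auc(mc.IndifferenceModel(b0=0.05, k=k)) < auc0


class TestBaselineSamplers:
    def test_grid_lattice_corners(self, grid, rng):
        offers = baseline_sampler("GRID", 9, grid, rng, CostType.RISK)
        assert len(offers) == 9
        costs = sorted({o.C for o in offers})
        rewards = sorted({o.r for o in offers})
        assert costs[0] == pytest.approx(0.02) and costs[-1] == pytest.approx(1.0)
        assert rewards[0] == pytest.approx(grid.reward_levels[0])
        assert rewards[-1] == pytest.approx(grid.reward_levels[-1])

    def test_grid_rejects_non_square(self, grid, rng):
        with pytest.raises(ValueError):
            baseline_sampler("GRID", 10, grid, rng, CostType.RISK)

    def test_random_uniform_marginal(self, grid):
        rng = np.random.default_rng(4)
        offers = baseline_sampler("RANDOM", 10_000, grid, rng, CostType.DELAY)
        counts = np.zeros(50)
        for o in offers:
            counts[grid.nearest_cost_index(o.C)] += 1
        freq = counts / len(offers)
        se = np.sqrt((1 / 50) * (49 / 50) / len(offers))
        assert np.all(np.abs(freq - 1 / 50) < 4 * se)

    def test_budget_64_is_the_per_type_session_budget(self, grid, rng):
        offers = baseline_sampler("GRID", 64, grid, rng, CostType.MENTAL_EFFORT)
        assert len(offers) == 64


class TestPersistence:
    def test_json_roundtrip_resumes_identically(self, grid):
        rng = np.random.default_rng(9)
        s1 = OTGSampler(OTGConfig(), grid)
        for _ in range(12):
            offer = s1.propose(CostType.RISK, rng)
            s1.record(offer, bool(rng.random() < 0.5))
        s2 = OTGSampler.from_json(s1.to_json())
        r1, r2 = np.random.default_rng(42), np.random.default_rng(42)
        for _ in range(5):
            assert s1.propose(CostType.RISK, r1) == s2.propose(CostType.RISK, r2)
        np.testing.assert_allclose(
            s1.models[CostType.RISK].posterior_cov, s2.models[CostType.RISK].posterior_cov
        )
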