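"""Synthetic agents, feedback, mood dynamics, and closed-loop sessions."""

import numpy as np
import pandas as pd
import pytest

import moodchoice as mc
from moodchoice.core import COST_TYPES, Condition, CostType, P_CORRECT, TrialSlot
from moodchoice.simulate import (AgentDistribution, MoodParams, agent_from_dict,
                                 agent_to_dict, sample_agent, simulate_mood_trace,
                                 simulate_quiz_feedback, simulate_session,
                                 simulate_experiment, write_cohort)


class TestSampleAgent:
    def test_degenerate_log_sd_gives_unit_weights(self, rng):
        agent = sample_agent(AgentDistribution(log_sd=0.0), rng)
        assert all(agent.params.k_cost[t] == 1.0 for t in COST_TYPES)
        assert agent.params.k_rew == 1.0

    def test_median_cost_weight_near_one(self):
        rng = np.random.default_rng(0)
        dist = AgentDistribution()
        ks = [sample_agent(dist, rng).params.k_cost[CostType.DELAY] for _ in range(4000)]
        assert 0.9 < np.median(ks) < 1.1

    def test_seed_determinism(self):
        a = sample_agent(AgentDistribution(), np.random.default_rng(7))
        b = sample_agent(AgentDistribution(), np.random.default_rng(7))
        assert agent_to_dict(a) == agent_to_dict(b)

    def test_positivity_flags(self):
        rng = np.random.default_rng(1)
        dist = AgentDistribution(beta0_positive=True, beta_mood_positive=True)
        for _ in range(50):
            agent = sample_agent(dist, rng)
            assert all(agent.params.beta0[t] >= 0 for t in COST_TYPES)
            assert agent.params.beta_mood >= 0

    def test_json_roundtrip(self, rng):
        agent = sample_agent(AgentDistribution(), rng)
        back = agent_from_dict(agent_to_dict(agent))
        assert agent_to_dict(back) == agent_to_dict(agent)


class TestQuizFeedback:
    @staticmethod
    def _slot(condition, p_correct, bias):
        return TrialSlot(0, condition, bias, p_correct, CostType.RISK)

    def test_always_positive_when_always_correct(self, rng):
        slot = self._slot(Condition.POSITIVE, 1.0 - 1e-12, 0.5)
        assert all(simulate_quiz_feedback(slot, rng)[1] for _ in range(200))

    def test_unbiased_rate_equals_p_correct(self):
        rng = np.random.default_rng(2)
        slot = self._slot(Condition.NEGATIVE, 0.216, 0.0)
        n = 50_000
        pos = sum(simulate_quiz_feedback(slot, rng)[1] for _ in range(n))
        se = np.sqrt(0.216 * (1 - 0.216) / n)
        assert abs(pos / n - 0.216) < 3.5 * se

    @pytest.mark.parametrize("p,bias", [(0.506, 0.5), (0.358, 0.25), (0.216, 0.0)])
    def test_feedback_rate_identity(self, p, bias):
        """Positive-feedback rate = p_correct + (1 - p_correct) * bias."""
        rng = np.random.default_rng(3)
        slot = self._slot(Condition.TRANSITION, p, bias)
        n = 50_000
        pos = sum(simulate_quiz_feedback(slot, rng)[1] for _ in range(n))
        expected = p + (1 - p) * bias
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(pos / n - expected) < 3.5 * se


class TestMoodTrace:
    def test_memoryless_noise_free(self, rng):
        mp = MoodParams(decay=0.0, gain_pos=0.05, gain_neg=0.09, noise_sd=0.0)
        trace = simulate_mood_trace([True, False, True], mp, rng)
        np.testing.assert_allclose(trace, [0.05, -0.09, 0.05])

    def test_geometric_limit_all_positive(self, rng):
        mp = MoodParams(decay=0.85, gain_pos=0.05, gain_neg=0.09, noise_sd=0.0)
        trace = simulate_mood_trace([True] * 200, mp, rng)
        assert trace[-1] == pytest.approx(0.05 / 0.15, rel=1e-6)

    def test_episode_slopes_have_induced_signs(self):
        """Mood climbs within positive episodes and falls (more steeply)
        within negative ones, on average over seeded sessions."""
        rng = np.random.default_rng(4)
        pos_slopes, neg_slopes = [], []
        for _ in range(20):
            sched = mc.make_session_schedule(rng)
            fb = [simulate_quiz_feedback(s, rng)[1] for s in sched.trials]
            trace = simulate_mood_trace(fb, MoodParams(), rng)
            z = (trace - trace.mean()) / trace.std()
            conds = [s.condition for s in sched.trials]
            for b in range(4):
                seg = slice(32 * b + 7, 32 * b + 25)
                slope = np.polyfit(np.arange(18), z[seg], 1)[0]
                (pos_slopes if conds[32 * b + 7] is Condition.POSITIVE else neg_slopes).append(slope)
        assert np.mean(pos_slopes) > 0
        assert np.mean(neg_slopes) < 0
        assert abs(np.mean(neg_slopes)) > abs(np.mean(pos_slopes))


@pytest.fixture(scope="module")
def agent():
    return sample_agent(AgentDistribution(beta0_positive=True, beta_mood_positive=True),
                        np.random.default_rng(10))


class TestSessions:
    def test_session_structure(self, agent):
        rng = np.random.default_rng(0)
        sched = mc.make_session_schedule(rng)
        log = simulate_session(agent, sched, "random", rng)
        assert len(log) == 128
        assert (log.groupby("cost_type").size() == 32).all()
        assert (log["rt"] > 0).all()
        np.testing.assert_allclose(log["mood_z"].mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(log["mood_z"].std(ddof=0), 1.0, atol=1e-9)

    def test_determinism(self, agent):
        sched = mc.make_session_schedule(5)
        a = simulate_session(agent, sched, "otg", np.random.default_rng(6))
        b = simulate_session(agent, sched, "otg", np.random.default_rng(6))
        pd.testing.assert_frame_equal(a, b)

    def test_no_mood_coupling_gives_null_contrast(self):
        """beta_mood = 0: costly-choice rates match between positive and
        negative episodes, on average over sessions."""
        rng = np.random.default_rng(1)
        agent = sample_agent(
            AgentDistribution(beta_mood_mean=0.0, beta_mood_sd=0.0, beta0_positive=True), rng)
        diffs = []
        for _ in range(40):
            sched = mc.make_session_schedule(rng)
            log = simulate_session(agent, sched, "random", rng)
            pos = log[log.condition == "positive"]["choice"].mean()
            neg = log[log.condition == "negative"]["choice"].mean()
            diffs.append(pos - neg)
        assert abs(np.mean(diffs)) < 0.03

    def test_positive_mood_bias_raises_costly_rate_in_positive_episodes(self, agent):
        assert agent.params.beta_mood > 0
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(40):
            sched = mc.make_session_schedule(rng)
            log = simulate_session(agent, sched, "random", rng)
            diffs.append(log[log.condition == "positive"]["choice"].mean()
                         - log[log.condition == "negative"]["choice"].mean())
        assert np.mean(diffs) > 0.02

    def test_otg_offers_uncorrelated_with_episodes(self, agent):
        """OTG-selected rewards and costs do not differ systematically
        between positive and negative episodes."""
        rng = np.random.default_rng(3)
        logs = []
        for s in range(20):
            sched = mc.make_session_schedule(rng)
            logs.append(simulate_session(agent, sched, "otg", rng, session=s))
        log = pd.concat(logs)
        r_diffs, c_diffs = [], []
        for _, s in log.groupby("session"):
            pos, neg = s[s.condition == "positive"], s[s.condition == "negative"]
            r_diffs.append(pos["r"].mean() - neg["r"].mean())
            c_diffs.append(pos["C"].mean() - neg["C"].mean())
        from scipy import stats

        assert stats.ttest_1samp(r_diffs, 0).pvalue > 0.01
        assert stats.ttest_1samp(c_diffs, 0).pvalue > 0.01

    def test_grid_sampler_session_covers_lattice(self, agent):
        rng = np.random.default_rng(8)
        sched = mc.make_session_schedule(rng)
        log = simulate_session(agent, sched, "grid", rng)
        assert len(log) == 128
        # each cost type's 32 offers are distinct lattice cells
        for t, sub in log.groupby("cost_type"):
            assert len(sub[["r", "C"]].drop_duplicates()) == 32

    def test_experiment_has_fresh_otg_and_auc_column(self, agent):
        rng = np.random.default_rng(4)
        log = simulate_experiment(agent, rng, n_sessions=2, sampler="otg")
        assert len(log) == 256
        assert log["auc"].notna().all()
        assert set(log["session"]) == {0, 1}

    def test_write_cohort(self, tmp_path, agent):
        rng = np.random.default_rng(5)
        log = simulate_experiment(agent, rng, n_sessions=1, sampler="random")
        write_cohort(tmp_path / "log.csv", tmp_path / "agents.json", log, [agent])
        df = pd.read_csv(tmp_path / "log.csv")
        assert len(df) == 128
        import json

        agents = json.loads((tmp_path / "agents.json").read_text())
        assert agents[0]["spec"] == agent.spec.code
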