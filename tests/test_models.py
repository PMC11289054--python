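"""Model equations: softmax, value updates, likelihood, generative agents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlreliability import (
    BanditConfig,
    ModelSpec,
    ParamSet,
    QState,
    choice_prob,
    make_agent,
    negative_log_likelihood,
    run_bandit_session,
    update,
)
from rlreliability.models import MODEL_SPECS

from conftest import make_trial_sequence


class TestChoiceProb:
    def test_equal_values_give_half(self):
        assert choice_prob(0.3, 0.3, 5.0) == 0.5

    def test_zero_temperature_gives_half(self):
        assert choice_prob(1.0, -1.0, 0.0) == 0.5

    def test_logistic_closed_form(self):
        # dQ = 1, tau = 2 -> 1/(1+e^-2)
        assert choice_prob(1.0, 0.0, 2.0) == pytest.approx(0.8807970779778823, abs=1e-12)

    def test_symmetry(self):
        assert choice_prob(0.4, -0.2, 3.0) == pytest.approx(
            1.0 - choice_prob(-0.2, 0.4, 3.0), abs=1e-12)


class TestUpdate:
    def test_zero_learning_rate_leaves_values_unchanged(self):
        q = QState.zeros(1)
        q.q[0] = [0.3, -0.2]
        spec = ModelSpec(2, "kappa_du", "bandit")
        p = ParamSet(tau=5, alpha_gain=0.0, alpha_loss=0.0, kappa=0.7)
        out = update(q, 0, 1, p, spec, block_valence=1)
        np.testing.assert_allclose(out.q, q.q)

    def test_single_step_half_learning_rate(self):
        spec = ModelSpec(1, "single", "bandit")
        out = update(QState.zeros(1), 0, 1, ParamSet(tau=5, alpha=0.5), spec, 1)
        assert out.q[0, 0] == pytest.approx(0.5)
        assert out.q[0, 1] == 0.0

    def test_bandit_gain_block_recodes_unchosen_zero_reward_as_plus_one(self):
        spec = ModelSpec(1, "full_du", "bandit")
        out = update(QState.zeros(1), 0, 0, ParamSet(tau=5, alpha=0.5), spec, 1)
        # r_chosen = 0 in a gain block -> r_unchosen = +1
        assert out.q[0, 1] == pytest.approx(0.5)

    def test_bandit_loss_block_recodes_unchosen_zero_reward_as_minus_one(self):
        spec = ModelSpec(1, "full_du", "bandit")
        out = update(QState.zeros(1), 0, 0, ParamSet(tau=5, alpha=0.5), spec, -1)
        assert out.q[0, 1] == pytest.approx(-0.5)

    def test_reversal_unchosen_reward_is_sign_flipped(self):
        spec = ModelSpec(1, "full_du", "reversal")
        out = update(QState.zeros(1), 0, 1, ParamSet(tau=5, alpha=0.5), spec, 0)
        assert out.q[0, 0] == pytest.approx(0.5)
        assert out.q[0, 1] == pytest.approx(-0.5)

    def test_invalid_reward_rejected(self):
        spec = ModelSpec(1, "single", "bandit")
        with pytest.raises(ValueError):
            update(QState.zeros(1), 0, 2, ParamSet(tau=5, alpha=0.5), spec, 1)

    @settings(max_examples=60, deadline=None)
    @given(
        rewards=st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=40),
        choices=st.lists(st.integers(0, 1), min_size=40, max_size=40),
        a_gain=st.floats(0, 1), a_loss=st.floats(0, 1), kappa=st.floats(0, 1),
    )
    def test_q_values_stay_in_unit_interval(self, rewards, choices, a_gain, a_loss, kappa):
        """Rewards in {-1,0,1} with rates in [0,1] can never push Q outside [-1,1]."""
        spec = ModelSpec(2, "kappa_du", "bandit")
        p = ParamSet(tau=5, alpha_gain=a_gain, alpha_loss=a_loss, kappa=kappa)
        q = QState.zeros(1)
        for r, c in zip(rewards, choices):
            q = update(q, c, r, p, spec, block_valence=1 if r >= 0 else -1)
            assert np.all(q.q >= -1.0) and np.all(q.q <= 1.0)


class TestLikelihood:
    def test_zero_temperature_gives_n_log_two_exactly(self, bandit_session, dual_spec):
        p = ParamSet(tau=0.0, alpha_gain=0.7, alpha_loss=0.2)
        assert negative_log_likelihood(p, bandit_session, dual_spec) == pytest.approx(
            160 * math.log(2), rel=1e-12)

    def test_three_trial_hand_oracle(self):
        """Trial-by-trial replay of a hand-built sequence, checked against an
        independent spreadsheet-style computation kept inline here."""
        session = make_trial_sequence("bandit", [
            (0, 1, 0, 1, False),   # choose A, win
            (0, 1, 0, 0, False),   # choose A, nothing
            (0, 1, 1, 1, False),   # choose B, win
        ])
        spec = ModelSpec(1, "single", "bandit")
        alpha, tau = 0.5, 5.0
        # oracle: replay by hand
        qa = qb = 0.0
        nll = 0.0
        for choice, reward in ((0, 1), (0, 0), (1, 1)):
            p_a = 1.0 / (1.0 + math.exp(-tau * (qa - qb)))
            nll -= math.log(p_a if choice == 0 else 1.0 - p_a)
            if choice == 0:
                qa += alpha * (reward - qa)
            else:
                qb += alpha * (reward - qb)
        got = negative_log_likelihood(ParamSet(tau=tau, alpha=alpha), session, spec)
        assert got == pytest.approx(nll, abs=1e-12)

    def test_timed_out_trials_are_skipped(self):
        base = [(0, 1, 0, 1, False), (0, 1, 0, 0, False), (0, 1, 1, 1, False)]
        with_timeout = base[:1] + [(0, 1, 0, 0, True)] + base[1:]
        spec = ModelSpec(1, "single", "bandit")
        p = ParamSet(tau=5.0, alpha=0.5)
        assert negative_log_likelihood(p, make_trial_sequence("bandit", with_timeout), spec) == \
            pytest.approx(negative_log_likelihood(p, make_trial_sequence("bandit", base), spec))

    def test_appending_a_trial_never_decreases_nll(self):
        spec = ModelSpec(1, "single", "bandit")
        p = ParamSet(tau=5.0, alpha=0.5)
        entries = [(0, 1, 0, 1, False), (0, 1, 1, 0, False), (1, 1, 0, 1, False)]
        prev = 0.0
        for i in range(1, len(entries) + 1):
            nll = negative_log_likelihood(p, make_trial_sequence("bandit", entries[:i]), spec)
            assert nll >= prev
            prev = nll

    def test_empty_session_rejected(self, bandit_session, dual_spec):
        from rlreliability import inject_timeouts

        dead = inject_timeouts(bandit_session, 1.0, seed=0)
        with pytest.raises(ValueError):
            negative_log_likelihood(ParamSet(tau=1, alpha_gain=.5, alpha_loss=.5),
                                    dead, dual_spec)


class TestModelEquivalences:
    """Nesting relations between the six variants, checked trial-for-trial."""

    def _sessions(self):
        out = []
        for seed in (1, 2, 3):
            agent = make_agent(ParamSet(tau=4, alpha_gain=.6, alpha_loss=.3),
                               ModelSpec(2, "single", "bandit"), seed=seed)
            out.append(run_bandit_session(agent, seed=seed + 50))
        return out

    @pytest.mark.parametrize("task", ["bandit", "reversal"])
    def test_kappa_zero_equals_no_double_update(self, task, bandit_session, reversal_session):
        s = bandit_session if task == "bandit" else reversal_session
        p_kdu = ParamSet(tau=4, alpha_gain=.6, alpha_loss=.3, kappa=0.0)
        p_single = ParamSet(tau=4, alpha_gain=.6, alpha_loss=.3)
        assert negative_log_likelihood(p_kdu, s, ModelSpec(2, "kappa_du", task)) == \
            pytest.approx(negative_log_likelihood(p_single, s, ModelSpec(2, "single", task)),
                          abs=1e-12)

    @pytest.mark.parametrize("task", ["bandit", "reversal"])
    def test_kappa_one_equals_full_double_update(self, task, bandit_session, reversal_session):
        s = bandit_session if task == "bandit" else reversal_session
        p_kdu = ParamSet(tau=4, alpha_gain=.6, alpha_loss=.3, kappa=1.0)
        p_du = ParamSet(tau=4, alpha_gain=.6, alpha_loss=.3)
        assert negative_log_likelihood(p_kdu, s, ModelSpec(2, "kappa_du", task)) == \
            pytest.approx(negative_log_likelihood(p_du, s, ModelSpec(2, "full_du", task)),
                          abs=1e-12)

    def test_equal_dual_rates_equal_single_rate(self, bandit_session):
        p_dual = ParamSet(tau=4, alpha_gain=.45, alpha_loss=.45)
        p_single = ParamSet(tau=4, alpha=.45)
        for rule in ("single", "full_du"):
            assert negative_log_likelihood(p_dual, bandit_session, ModelSpec(2, rule, "bandit")) == \
                pytest.approx(
                    negative_log_likelihood(p_single, bandit_session, ModelSpec(1, rule, "bandit")),
                    abs=1e-12)

    def test_model_space_has_six_variants(self):
        specs = MODEL_SPECS("bandit")
        assert len(specs) == 6
        assert {s.n_params for s in specs.values()} == {2, 3, 4}


class TestAgent:
    def test_zero_temperature_agent_chooses_uniformly(self):
        agent = make_agent(ParamSet(tau=0.0, alpha=0.5), ModelSpec(1, "single", "bandit"),
                           seed=3)
        cfg = BanditConfig(presentations_per_pair=1250)
        s = run_bandit_session(agent, cfg, seed=4)
        frac = np.mean([t.chosen_index for t in s.trials])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(s))

    def test_greedy_agent_locks_onto_advantageous_option(self):
        # deterministic feedback, maximal learning rate, near-greedy choice:
        # after the first differentiating outcome the agent stays put
        cfg = BanditConfig(congruent_feedback_probs=(1.0, 1.0), first_block_valence="gain")
        agent = make_agent(ParamSet(tau=20.0, alpha=1.0), ModelSpec(1, "single", "bandit"),
                           seed=5)
        s = run_bandit_session(agent, cfg, seed=6)
        # a zero reward leaves Q untouched, so differentiation starts at the
        # first nonzero outcome of a pair; from then on the choice is fixed
        differentiated = set()
        for t in s.trials:
            if t.pair_id in differentiated:
                assert t.choice == t.correct_option
            if t.reward != 0:
                differentiated.add(t.pair_id)

    def test_same_seed_same_parameters_identical_session(self, dual_params, dual_spec):
        a = run_bandit_session(make_agent(dual_params, dual_spec, seed=7), seed=8)
        b = run_bandit_session(make_agent(dual_params, dual_spec, seed=7), seed=8)
        assert a.to_frame().equals(b.to_frame())

    def test_generating_parameters_beat_perturbed_on_long_session(self):
        """Self-consistency: on a long simulated session the generating
        parameters fit no worse (on average) than perturbed ones."""
        spec = ModelSpec(2, "single", "bandit")
        truth = ParamSet(tau=5.0, alpha_gain=0.7, alpha_loss=0.25)
        cfg = BanditConfig(presentations_per_pair=1250)
        agent = make_agent(truth, spec, seed=9)
        s = run_bandit_session(agent, cfg, seed=10)
        nll_true = negative_log_likelihood(truth, s, spec)
        for pert in (ParamSet(tau=9.0, alpha_gain=0.7, alpha_loss=0.25),
                     ParamSet(tau=5.0, alpha_gain=0.3, alpha_loss=0.25),
                     ParamSet(tau=5.0, alpha_gain=0.7, alpha_loss=0.65)):
            assert nll_true < negative_log_likelihood(pert, s, spec)
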