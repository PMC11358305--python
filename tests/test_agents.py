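"""Choice-probability and update rules of the EXP and INF models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revalue.agents import (
    V_A,
    ExpParams,
    ExpState,
    InfParams,
    InfState,
    exp_choice_prob,
    exp_update,
    inf_choice_prob,
    inf_update,
    make_agent,
    simulate_choices,
)
from revalue.behavior_metrics import optimal_indicators
from revalue.core_io import STIMULI, ValidationError
from revalue.task_engine import FamiliarTaskSpec, NovelTaskSpec

PAIRS = [(a, b) for a in STIMULI for b in STIMULI if a != b]


def state_with(values) -> ExpState:
    return ExpState(V=np.array(values, dtype=float))


class TestExpChoice:
    def test_equal_values_give_half(self):
        s = state_with([2.0, 2.0, 0, 0, 0])
        for beta in (0.0, 0.7, 5.0):
            assert exp_choice_prob(s, ("S1", "S2"), beta) == 0.5

    def test_beta_zero_is_uniform(self):
        s = state_with([5, 1, 3, 2, 4])
        assert exp_choice_prob(s, ("S1", "S2"), 0.0) == 0.5

    def test_hand_value_softmax(self):
        # V = (3, 1), beta = 1: p = 1 / (1 + e^-2)
        s = state_with([3, 1, 0, 0, 0])
        assert exp_choice_prob(s, ("S1", "S2"), 1.0) == pytest.approx(
            1 / (1 + math.exp(-2)), abs=1e-12)
        assert exp_choice_prob(s, ("S1", "S2"), 1.0) == pytest.approx(0.88080, abs=5e-6)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValidationError):
            exp_choice_prob(state_with([0] * 5), ("S1", "S2"), -0.1)

    def test_large_beta_does_not_overflow(self):
        s = state_with([5, 1, 0, 0, 0])
        p = exp_choice_prob(s, ("S1", "S2"), 500.0)
        assert 0 < p <= 1.0

    @given(vi=st.floats(-5, 5), vj=st.floats(-5, 5), beta=st.floats(0, 10))
    @settings(derandomize=True, deadline=None)
    def test_complementary_over_the_pair(self, vi, vj, beta):
        s = state_with([vi, vj, 0, 0, 0])
        p = exp_choice_prob(s, ("S1", "S2"), beta)
        q = exp_choice_prob(s, ("S2", "S1"), beta)
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestExpUpdate:
    def test_alpha_zero_leaves_state_unchanged(self):
        s = state_with([1, 2, 3, 4, 5])
        assert np.array_equal(exp_update(s, "S3", 5, 0.0).V, s.V)

    def test_zero_prediction_error_is_fixed_point(self):
        s = state_with([0, 0, 4, 0, 0])
        assert np.array_equal(exp_update(s, "S3", 4, 0.3).V, s.V)

    def test_hand_arithmetic(self):
        s = state_with([0.0] * 5)
        assert exp_update(s, "S2", 5, 0.1).V[1] == pytest.approx(0.5)

    def test_only_chosen_value_changes(self):
        s = state_with([1, 1, 1, 1, 1])
        out = exp_update(s, "S4", 5, 0.5)
        assert out.V[3] == pytest.approx(3.0)
        assert np.array_equal(np.delete(out.V, 3), np.ones(4))

    @given(v=st.floats(-5, 10), r=st.integers(1, 5),
           alpha=st.floats(0.001, 1.0))
    @settings(derandomize=True, deadline=None)
    def test_contraction_toward_reward(self, v, r, alpha):
        s = state_with([v, 0, 0, 0, 0])
        v2 = exp_update(s, "S1", r, alpha).V[0]
        assert abs(v2 - r) == pytest.approx((1 - alpha) * abs(v - r), abs=1e-9)


class TestInfChoice:
    def test_w_one_equals_exp_on_pattern_a_values(self):
        exp_state = ExpState(V=V_A.copy())
        for pair in PAIRS:
            for beta in (0.0, 0.5, 2.0):
                assert inf_choice_prob(InfState(w=1.0), pair, beta) == \
                    exp_choice_prob(exp_state, pair, beta)

    def test_symmetric_pair_at_half_confidence(self):
        # V_A(S1) = V_B(S5) = 1 and V_A(S5) = V_B(S1) = 5, so at w = 0.5 the
        # two mixture components are mirror images
        for beta in (0.0, 1.0, 3.0):
            assert inf_choice_prob(InfState(w=0.5), ("S1", "S5"), beta) == \
                pytest.approx(0.5, abs=1e-12)

    def test_hand_value_mixture(self):
        # pair (S1, S3), w = 0.7, beta = 1:
        # 0.7 * 1/(1+e^2) + 0.3 * 1/(1+e^-2)
        expected = 0.7 / (1 + math.exp(2)) + 0.3 / (1 + math.exp(-2))
        assert inf_choice_prob(InfState(w=0.7), ("S1", "S3"), 1.0) == \
            pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3477, abs=5e-5)

    def test_w_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            inf_choice_prob(InfState(w=1.2), ("S1", "S2"), 1.0)

    @given(w=st.floats(0, 1), beta=st.floats(0, 10))
    @settings(derandomize=True, deadline=None)
    def test_complementary_over_the_pair(self, w, beta):
        p = inf_choice_prob(InfState(w=w), ("S2", "S4"), beta)
        q = inf_choice_prob(InfState(w=w), ("S4", "S2"), beta)
        assert 0.0 < p < 1.0 or beta == 0
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestInfUpdate:
    def test_middle_stimulus_has_zero_gradient(self):
        # V_A(S3) = V_B(S3) = 3
        for r in (1, 5):
            assert inf_update(InfState(w=0.31), "S3", r, 0.2).w == 0.31

    def test_hand_arithmetic(self):
        # w=0.5, alpha=0.05, chosen S1 (V_A=1, V_B=5), r=5:
        # expected = 3; delta = -0.05 * (3-5) * (1-5) = -0.4
        assert inf_update(InfState(w=0.5), "S1", 5, 0.05).w == pytest.approx(0.1)

    def test_clipped_exactly_to_zero(self):
        out = inf_update(InfState(w=0.1), "S1", 5, 0.05)
        # raw update: 0.1 - 0.05*(0.1*1+0.9*5-5)*(-4) = 0.1 - 0.088 = 0.012 > 0
        out2 = inf_update(InfState(w=0.5), "S1", 5, 0.2)  # 0.5 - 1.6 < 0
        assert out2.w == 0.0
        assert 0.0 <= out.w <= 1.0

    def test_clipped_exactly_to_one(self):
        assert inf_update(InfState(w=0.5), "S5", 5, 0.2).w == 1.0

    @given(w=st.floats(0, 1), stim=st.sampled_from(STIMULI),
           r=st.integers(1, 5), alpha=st.floats(0, 1))
    @settings(derandomize=True, deadline=None)
    def test_w_stays_in_unit_interval(self, w, stim, r, alpha):
        assert 0.0 <= inf_update(InfState(w=w), stim, r, alpha).w <= 1.0


class TestSimulation:
    def test_fixed_seed_reproduces_session(self):
        def make():
            return simulate_choices("INF", InfParams(alpha=0.05, beta=1.5),
                                    FamiliarTaskSpec(), np.random.default_rng(42))

        assert make() == make()

    def test_exp_alpha_zero_stays_at_chance(self):
        s = simulate_choices("EXP", ExpParams(alpha=0.0, beta=2.0),
                             NovelTaskSpec(), np.random.default_rng(0))
        # values never leave zero, so choices are fair coin flips
        rate = optimal_indicators(s).mean()
        assert abs(rate - 0.5) < 0.1

    def test_inf_agent_recovers_fast_after_familiar_reversals(self):
        # qualitative adaptation property: within 5 trials of a reversal the
        # optimal-choice rate is back above 0.8 (and stays there)
        recovered, first = [], []
        for seed in range(10):
            s = simulate_choices("INF", InfParams(alpha=0.05, beta=1.5),
                                 FamiliarTaskSpec(), np.random.default_rng(seed))
            ind = optimal_indicators(s)
            for b in s.reversal_trials():
                first.append(ind[b - 1])
                recovered.extend(ind[b - 1 + 4 : b - 1 + 10])
        assert np.mean(recovered) > 0.8
        assert np.mean(first) < 0.3  # reversal is unsignalled: 1st trial fails

    def test_silencing_flag_uses_post_reversal_alpha(self):
        agent = make_agent("EXP", ExpParams(alpha=0.2, beta=1.0, alpha_post=0.0))
        agent.observe("S1", 5, post_reversal=True)
        assert agent.state.V[0] == 0.0
        agent.observe("S1", 5, post_reversal=False)
        assert agent.state.V[0] == pytest.approx(1.0)
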