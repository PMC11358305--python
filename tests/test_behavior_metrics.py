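"""Optimal-choice rates, phase windows, event extraction and Eq.-style stats."""

import numpy as np
import pytest

from revalue.behavior_metrics import (
    DevaluationCounts,
    block_optimal_rate,
    extract_experience_events,
    extract_inference_trials,
    metrics_table,
    optimal_choice_indicator,
    optimal_indicators,
    phase_rates,
    proportion_shifted,
)
from revalue.core_io import ValidationError

from conftest import (
    inference_trial_fixture,
    negative_experience_fixture,
    positive_experience_fixture,
    scripted_session,
)


def all_optimal_familiar(n=30, boundaries=frozenset()):
    """Scripted session whose choice is always the in-force better option."""
    pairs = [("S1", "S5"), ("S2", "S4")] * (n // 2)
    choices = []
    pattern = "A"
    for t, pair in enumerate(pairs, start=1):
        if t in boundaries:
            pattern = "B" if pattern == "A" else "A"
        key = (lambda s: int(s[1:])) if pattern == "A" else (lambda s: 6 - int(s[1:]))
        choices.append(max(pair, key=key))
    return scripted_session("FAMILIAR", pairs, choices, set(boundaries))


class TestIndicators:
    def test_choosing_larger_reward_scores_one(self):
        s = all_optimal_familiar()
        assert optimal_indicators(s).tolist() == [1] * 30

    def test_choosing_smaller_reward_scores_zero(self):
        pairs = [("S3", "S5")] * 10
        s = scripted_session("FAMILIAR", pairs, ["S3"] * 10, set())
        assert optimal_indicators(s).tolist() == [0] * 10

    def test_optimality_judged_by_in_force_map(self):
        # keep choosing the formerly better stimulus after a reversal -> 0
        pairs = [("S1", "S5")] * 10
        s = scripted_session("FAMILIAR", pairs, ["S5"] * 10, {6})
        assert optimal_indicators(s).tolist() == [1] * 5 + [0] * 5


class TestBlocks:
    def test_all_optimal_blocks_are_one(self):
        assert block_optimal_rate(all_optimal_familiar()).tolist() == [1.0] * 3

    def test_alternating_choices_give_half(self):
        pairs = [("S1", "S5")] * 20
        choices = ["S5", "S1"] * 10
        s = scripted_session("FAMILIAR", pairs, choices, set())
        assert block_optimal_rate(s).tolist() == [0.5, 0.5]

    def test_trailing_partial_block_dropped(self):
        pairs = [("S1", "S5")] * 25
        s = scripted_session("FAMILIAR", pairs, ["S5"] * 25, set())
        assert len(block_optimal_rate(s)) == 2

    def test_novel_session_yields_30_blocks(self, exp_novel_sessions):
        assert len(block_optimal_rate(exp_novel_sessions[0])) == 30


class TestPhaseRates:
    def test_novel_windows(self, exp_novel_sessions):
        s = exp_novel_sessions[0]
        ind = optimal_indicators(s)
        rates = phase_rates(s)
        assert rates["Pre"] == pytest.approx(ind[:90].mean())
        assert rates["PoE"] == pytest.approx(ind[90:190].mean())
        assert rates["PoL"] == pytest.approx(ind[190:300].mean())

    def test_familiar_phase_means_average_across_reversals(self, inf_familiar_sessions):
        s = inf_familiar_sessions[0]
        boundaries = [t - 1 for t in s.reversal_trials()]
        assert len(boundaries) >= 2
        ind = optimal_indicators(s)
        per_rev = [ind[b : b + 5].mean() for b in boundaries]
        assert phase_rates(s)["PoE"] == pytest.approx(np.mean(per_rev))

    def test_all_optimal_session_scores_one_everywhere(self):
        s = all_optimal_familiar(n=30, boundaries=frozenset({16}))
        assert phase_rates(s) == {"Pre": 1.0, "PoE": 1.0, "PoL": 1.0}

    def test_no_reversal_is_an_error(self):
        s = all_optimal_familiar()
        with pytest.raises(ValidationError):
            phase_rates(s)


class TestExperienceEvents:
    def test_positive_worked_example_indices(self):
        events, rate = extract_experience_events(positive_experience_fixture(),
                                                 "positive")
        assert len(events) == 1
        ev = events[0]
        assert (ev.option, ev.nonchoice_trial, ev.event_trial, ev.evaluation_trial) \
            == ("S1", 12, 15, 18)
        assert rate == 1.0

    def test_negative_worked_example_indices(self):
        events, rate = extract_experience_events(negative_experience_fixture(),
                                                 "negative")
        assert len(events) == 1
        ev = events[0]
        assert (ev.option, ev.nonchoice_trial, ev.event_trial, ev.evaluation_trial) \
            == ("S5", 12, 15, 17)
        assert rate == 1.0

    def test_agent_always_taking_high_option_has_no_positive_events(self):
        # S1 and S2 (post-reversal 5 and 4 drops) chosen whenever offered
        pre = [(("S1", "S2"), "S1")] * 10
        poe = [(("S1", "S3"), "S1"), (("S2", "S4"), "S2"), (("S1", "S5"), "S1"),
               (("S2", "S5"), "S2")] * 5
        script = pre + poe
        s = scripted_session("NOVEL", [p for p, _ in script],
                             [c for _, c in script], {11})
        events, rate = extract_experience_events(s, "positive")
        assert events == []
        assert np.isnan(rate)

    def test_one_event_per_option(self):
        # repeated nonchoice/choice cycles of S1 still yield a single event
        pre = [(("S2", "S3"), "S2")] * 10
        poe = [(("S1", "S3"), "S3"), (("S1", "S4"), "S1"),
               (("S1", "S3"), "S3"), (("S1", "S4"), "S1")] * 5
        script = pre + poe
        s = scripted_session("NOVEL", [p for p, _ in script],
                             [c for _, c in script], {11})
        events, _ = extract_experience_events(s, "positive")
        assert [e.option for e in events] == ["S1"]
        assert events[0].event_trial == 12


class TestInferenceTrials:
    def test_worked_example_indices(self):
        extractions, inf_rate, first_rate = extract_inference_trials(
            inference_trial_fixture())
        assert len(extractions) == 1
        e = extractions[0]
        assert (e.first_trial, e.inference_trial) == (11, 14)
        assert (e.first_optimal, e.inference_optimal) == (0, 1)
        assert (inf_rate, first_rate) == (1.0, 0.0)

    def test_pairs_sharing_one_stimulus_are_excluded(self):
        _, _, _ = extract_inference_trials(inference_trial_fixture())
        s = inference_trial_fixture()
        first_pair = set(s.trials[10].pair)
        chosen_inference = s.trials[13].pair
        assert not (set(chosen_inference) & first_pair)
        for skipped in (s.trials[11].pair, s.trials[12].pair):
            assert set(skipped) & first_pair

    def test_search_stops_at_next_reversal(self):
        # reversal at 11 with no disjoint pair before the next reversal at 16
        pre = [(("S1", "S2"), "S1")] * 10
        post = [(("S2", "S4"), "S4"), (("S2", "S1"), "S2"), (("S4", "S5"), "S4"),
                (("S2", "S3"), "S2"), (("S4", "S3"), "S4"),
                (("S1", "S3"), "S1")] + [(("S1", "S2"), "S1")] * 4
        script = pre + post
        s = scripted_session("FAMILIAR", [p for p, _ in script],
                             [c for _, c in script], {11, 16})
        extractions, _, _ = extract_inference_trials(s)
        assert extractions[0].inference_trial is None
        assert extractions[1].first_trial == 16


class TestProportionShifted:
    def test_no_shift_is_zero(self):
        assert proportion_shifted(DevaluationCounts(20, 20, 15, 15)) == 0.0

    def test_complete_shift_is_one(self):
        assert proportion_shifted(DevaluationCounts(20, 0, 15, 0)) == 1.0

    def test_worked_arithmetic(self):
        assert proportion_shifted(DevaluationCounts(20, 10, 20, 5)) == \
            pytest.approx(0.625)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            proportion_shifted(DevaluationCounts(0, 3, 0, 2))


def test_metrics_table_has_task_specific_columns(exp_novel_sessions,
                                                 inf_familiar_sessions):
    df = metrics_table(exp_novel_sessions[:2] + inf_familiar_sessions[:2])
    assert len(df) == 4
    novel = df[df["task"] == "NOVEL"]
    familiar = df[df["task"] == "FAMILIAR"]
    assert novel["negative_event_rate"].notna().any()
    assert familiar["inference_rate"].notna().all()
    assert {"Pre", "PoE", "PoL"} <= set(df.columns)
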