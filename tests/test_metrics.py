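"""Behavioral metrics: criterion, curves, inflection, switch costs, search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from setshift import metrics as m


class TestTrialsToCriterion:
    def test_all_correct_block_reaches_criterion_at_trial_one(self):
        assert m.trials_to_criterion([1] * 35) == 1

    def test_all_incorrect_block_is_censored(self):
        assert m.trials_to_criterion([0] * 60) is None

    def test_window_must_be_complete(self):
        # 10 subsequent trials do not exist after trial 1 in a 10-trial block
        assert m.trials_to_criterion([1] * 10) is None
        assert m.trials_to_criterion([1] * 11) == 1

    def test_first_qualifying_window_located(self):
        # Trials 6..15 hold 8 correct of 10 (0.8 > 0.7); no earlier window does.
        seq = [0, 0, 0, 0, 0] + [1, 1, 1, 1, 0, 1, 1, 1, 0, 1] + [0] * 10
        assert m.trials_to_criterion_bruteforce(seq) == 5
        assert m.trials_to_criterion(seq) == 5

    def test_exactly_seventy_percent_does_not_qualify(self):
        seq = [0] + [1] * 7 + [0] * 3 + [0] * 10
        # window after trial 1: seven of ten correct = 0.7, not > 0.7
        assert m.trials_to_criterion(seq) != 1

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, seq):
        assert m.trials_to_criterion(seq) == m.trials_to_criterion_bruteforce(seq)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            m.trials_to_criterion([])


class TestLearningCurve:
    def test_constant_input_invariant_under_smoothing(self):
        curve = m.learning_curve([[1] * 30, [1] * 30])
        assert np.allclose(curve["accuracy"], 1.0)
        assert np.allclose(curve["se"].iloc[:30], 0.0)

    def test_step_function_ramp_hand_convolved(self):
        """A 0-to-1 step at trial 10 smoothed with a 5-trial window ramps
        linearly over trials 8-12."""
        block = [0] * 9 + [1] * 11
        curve = m.learning_curve([block, block], window=5)
        expected = {8: 0.2, 9: 0.4, 10: 0.6, 11: 0.8, 12: 1.0}
        for trial, value in expected.items():
            assert curve.loc[curve["trial"] == trial, "accuracy"].iloc[0] == pytest.approx(value)

    def test_first_three_trials_left_raw(self):
        block = [1, 0, 1] + [0] * 17
        curve = m.learning_curve([block], window=5)
        assert list(curve["accuracy"].iloc[:3]) == [1.0, 0.0, 1.0]

    def test_chance_logs_fluctuate_about_one_third(self, rng):
        blocks = [(rng.random(60) < 1 / 3).astype(int) for _ in range(300)]
        curve = m.learning_curve(blocks)
        assert abs(curve["accuracy"].mean() - 1 / 3) < 0.02

    def test_single_block_flags_undefined_se(self):
        curve = m.learning_curve([[1] * 20])
        assert curve["se"].isna().all()


class TestPlateauAccuracy:
    def test_all_correct_block(self):
        assert m.plateau_accuracy([1] * 30, 1) == 1.0

    def test_correct_only_inside_window(self):
        seq = [0] + [1] * 10 + [0] * 10
        assert m.plateau_accuracy(seq, 1) == 0.0

    def test_hand_built_post_window_count(self):
        seq = [1] * 13 + [1] * 9 + [0] * 3  # 12 trials after trial 1 + window 10
        t = 3
        post = seq[t + 10:]
        assert len(post) == 12 and sum(post) == 9
        assert m.plateau_accuracy(seq, t) == pytest.approx(0.75)

    def test_censored_or_short_blocks_undefined(self):
        assert m.plateau_accuracy([1] * 30, None) is None
        assert m.plateau_accuracy([1] * 11, 1) is None


class TestRTInflection:
    def test_strictly_decreasing_curve_found_at_three(self):
        curve = [900, 910, 905, 890, 870, 850]
        assert m.rt_inflection_trial(curve) == 3

    def test_rise_through_eight_then_fall(self):
        curve = [800, 810, 820, 830, 840, 850, 860, 870, 865, 855, 845]
        assert m.rt_inflection_trial(curve) == 9

    def test_flat_curve_censored(self):
        assert m.rt_inflection_trial([900.0] * 12) is None

    def test_trial_two_excluded(self):
        curve = [900, 880, 890, 895, 890, 880, 870]
        # decline at trial 2 is ignored; first admissible sustained decline is 5
        assert m.rt_inflection_trial(curve) == 5

    def test_single_dip_without_sustained_run_skipped(self):
        curve = [900, 905, 895, 910, 915, 920, 925, 930]
        assert m.rt_inflection_trial(curve) is None


class TestSessionThirds:
    def test_partition_is_exhaustive_and_disjoint(self):
        thirds = [m.session_third(b) for b in range(1, 22)]
        assert thirds == [1] * 7 + [2] * 7 + [3] * 7

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.session_third(22)


def _frl_rows(choices, target_dim="color", target="red", load="low",
              switch="intradimensional", block=2, subject="s1", session=0):
    """Hand-built FRL block rows; choices = list of (chosen_features, correct, rewarded)."""
    return [
        {
            "subject": subject, "session": session, "dose": "vehicle",
            "task": "FRL", "block": block, "trial_in_block": i + 1,
            "load": load, "target_feature": target, "target_dimension": target_dim,
            "switch_type": switch, "set_size": 0, "mean_shared_features": np.nan,
            "objects": "", "choice_index": 0, "chosen_features": feats,
            "correct": c, "rewarded": r, "rt_ms": 500.0,
        }
        for i, (feats, c, r) in enumerate(choices)
    ]


class TestPerseverativeErrors:
    def test_hand_annotated_block(self):
        """Trials 3 and 5 repeat the unrewarded color chosen at trial 1; the
        repeated feature is in the target dimension, trial 6 repeats an
        unrewarded pattern (distractor dimension)."""
        rows = _frl_rows(
            [
                ("color=blue|pattern=dotted", 0, 0),
                ("color=red|pattern=wavy", 1, 1),
                ("color=blue|pattern=solid", 0, 0),
                ("color=red|pattern=grid", 1, 1),
                ("color=blue|pattern=grid", 0, 0),
                ("color=yellow|pattern=dotted", 0, 0),
            ],
            load="high",
        )
        log = pd.DataFrame(rows)
        t, d, errors = m._block_perseveration(log)
        assert t == 2  # trials 3 and 5 repeat unrewarded 'blue'
        assert errors == 4
        assert d == 1  # trial 6 repeats unrewarded 'dotted' ('grid' was rewarded)
        out = m.perseverative_errors(log)
        assert out["persev_target_per_trial"].iloc[0] == pytest.approx(2 / 6)
        assert out["persev_target_per_error"].iloc[0] == pytest.approx(2 / 4)

    def test_agent_that_never_repeats_scores_zero(self):
        rows = _frl_rows(
            [
                ("color=blue", 0, 0),
                ("color=yellow", 0, 0),
                ("color=green", 0, 0),
                ("color=red", 1, 1),
            ]
        )
        out = m.perseverative_errors(pd.DataFrame(rows))
        assert out["persev_target"].iloc[0] == 0.0
        assert out["persev_distractor"].iloc[0] == 0.0

    def test_proportions_bounded_by_error_rate(self, vehicle_log):
        out = m.perseverative_errors(vehicle_log)
        frl = vehicle_log[vehicle_log["task"] == "FRL"]
        error_rate = 1 - frl.groupby("session")["correct"].mean()
        for _, row in out.iterrows():
            err = error_rate.loc[row["session"]]
            assert 0.0 <= row["persev_target"] <= err
            assert 0.0 <= row["persev_distractor"] <= err
            assert row["persev_target_per_error"] <= 1.0

    def test_invalid_denominator_rejected(self, vehicle_log):
        with pytest.raises(ValueError):
            m.perseverative_errors(vehicle_log, denominator="sessions")


class TestSwitchCosts:
    def test_grouping_identity(self):
        bm = pd.DataFrame(
            {
                "switch_type": ["extradimensional"] * 2 + ["intradimensional"] * 2
                + ["novel_dimension", "first_block"],
                "trials_to_criterion": [4, 4, 9, 9, 30, 2],
            }
        )
        out = m.switch_cost_metrics(bm).set_index("switch_type")
        assert out.loc["extradimensional", "mean"] == 4
        assert out.loc["intradimensional", "mean"] == 9
        assert "novel_dimension" not in out.index
        with_novel = m.switch_cost_metrics(bm, include_novel=True).set_index("switch_type")
        assert with_novel.loc["novel_dimension", "mean"] == 30

    def test_censored_blocks_counted_but_not_averaged(self):
        bm = pd.DataFrame(
            {
                "switch_type": ["extradimensional"] * 3,
                "trials_to_criterion": [4.0, np.nan, 6.0],
            }
        )
        out = m.switch_cost_metrics(bm).iloc[0]
        assert out["mean"] == 5.0 and out["n_learned"] == 2 and out["n_blocks"] == 3


def _vs_rows(trials, block=0, subject="s1", session=0, task="VS"):
    """trials = list of (set_size, mean_shared, correct, rt_ms)."""
    return [
        {
            "subject": subject, "session": session, "dose": "vehicle",
            "task": task, "block": block, "trial_in_block": i + 1,
            "load": "", "target_feature": "t", "target_dimension": "",
            "switch_type": "", "set_size": s, "mean_shared_features": sh,
            "objects": "", "choice_index": 0, "chosen_features": "",
            "correct": c, "rewarded": c, "rt_ms": rt,
        }
        for i, (s, sh, c, rt) in enumerate(trials)
    ]


class TestVSSetSizeEffects:
    def test_exact_slope_on_noiseless_linear_input(self):
        trials = []
        for s, rt in zip((3, 6, 9, 12), (1000.0, 1300.0, 1600.0, 1900.0)):
            trials += [(s, 1.0, 1, rt)] * 5
        per_size, slopes = m.vs_set_size_effects(pd.DataFrame(_vs_rows(trials)))
        assert slopes["rt_slope"].iloc[0] == pytest.approx(100.0)  # ms per distractor
        assert slopes["accuracy_slope"].iloc[0] == pytest.approx(0.0)
        assert not slopes["incomplete_sizes"].iloc[0]

    def test_missing_set_size_flagged(self):
        trials = [(s, 1.0, 1, 1000.0 + 10 * s) for s in (3, 6, 9)] * 2
        _, slopes = m.vs_set_size_effects(pd.DataFrame(_vs_rows(trials)))
        assert slopes["incomplete_sizes"].iloc[0]
        assert slopes["rt_slope"].iloc[0] == pytest.approx(10.0)

    def test_generative_slope_recovered_from_simulation(self, vehicle_log):
        """The agent's search times are generated with a 57 ms/distractor
        increment; the fitted set-size slope recovers it."""
        _, slopes = m.vs_set_size_effects(vehicle_log)
        assert abs(slopes["rt_slope"].mean() - 57.0) < 6.0

    def test_correct_trials_only_enter_rt_means(self):
        trials = [(3, 1.0, 1, 1000.0), (3, 1.0, 0, 9000.0),
                  (6, 1.0, 1, 1300.0), (9, 1.0, 1, 1600.0), (12, 1.0, 1, 1900.0)]
        per_size, _ = m.vs_set_size_effects(pd.DataFrame(_vs_rows(trials)))
        assert per_size.loc[per_size["set_size"] == 3, "mean_rt"].iloc[0] == 1000.0


class TestVSSimilarityEffects:
    def test_exact_recovery_on_hand_built_log(self):
        trials = [(3, 0.0, 1, 1000.0), (3, 0.0, 1, 1100.0),
                  (3, 1.0, 1, 1300.0), (3, 2.0, 0, 1500.0), (3, 2.0, 1, 1600.0)]
        out = m.vs_similarity_effects(pd.DataFrame(_vs_rows(trials)))
        out = out.set_index("similarity")
        assert out.loc["low", "mean_rt"] == pytest.approx(1050.0)
        assert out.loc["medium", "mean_rt"] == pytest.approx(1300.0)
        assert out.loc["high", "accuracy"] == pytest.approx(0.5)

    def test_similarity_hurts_accuracy_in_simulation(self, vehicle_log):
        out = m.vs_similarity_effects(vehicle_log)
        acc = out.groupby("similarity")["accuracy"].mean()
        assert acc["low"] >= acc["high"]


class TestSpeedOfProcessing:
    def test_mean_familiarization_rt(self):
        rts = [400.0, 450, 500, 550, 600, 400, 450, 500, 550, 600]
        rows = _vs_rows([(0, np.nan, 1, rt) for rt in rts], task="VS_familiarization")
        out = m.speed_of_processing(pd.DataFrame(rows))
        assert out["mean_familiarization_rt"].iloc[0] == pytest.approx(np.mean(rts))
        assert out["n_trials"].iloc[0] == 10

    def test_missing_familiarization_flagged(self):
        rows = _vs_rows([(3, 1.0, 1, 1000.0)])
        with pytest.raises(ValueError):
            m.speed_of_processing(pd.DataFrame(rows))


class TestBlockAndSessionTables:
    def test_block_metrics_consistency(self, vehicle_log):
        bm = m.compute_block_metrics(vehicle_log)
        assert set(bm["block"]) == set(range(1, 22))
        assert bm["n_trials"].between(35, 60).all()
        learned = bm[bm["criterion_reached"]]
        assert (learned["trials_to_criterion"] >= 1).all()
        plateau = bm["plateau_accuracy"].dropna()
        assert plateau.between(0, 1).all()
        assert (bm["persev_target_dim_errors"] <= bm["total_errors"]).all()
        assert (bm["persev_distractor_dim_errors"] <= bm["total_errors"]).all()

    def test_session_metrics_thirds_partition(self, vehicle_log):
        bm = m.compute_block_metrics(vehicle_log)
        counts = bm.groupby(["session", "third"]).size().unstack()
        assert (counts == 7).all().all()
        sm = m.compute_session_metrics(vehicle_log)
        assert sm["criterion_reached_prop"].between(0, 1).all()
        assert len(sm) == vehicle_log["session"].nunique()
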