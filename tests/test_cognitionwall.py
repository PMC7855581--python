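"""Discrimination/reversal scoring against counting and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import stream_from_labels

from phenocage.cognitionwall import (
    RL_DAY_S,
    activity_measures,
    classify_rl_errors,
    entrance_bias,
    entries_to_criterion,
    fr5_reward_ledger,
    km_survival,
    split_phases,
    split_rl_days,
)
from phenocage.core import (
    ConfigurationError,
    CriterionResult,
    TaskSchedule,
    Track,
    ValidationError,
)

ENT = ["left", "middle", "right"]


def brute_force_criterion(labels, target, window, threshold):
    """Independent O(n*window) re-scan of the moving-window criterion."""
    correct = [lab == target for lab in labels]
    for k in range(window, len(labels) + 1):
        if sum(correct[k - window:k]) / window >= threshold - 1e-12:
            return k
    return None


class TestEntranceBias:
    def test_all_left(self, make_stream):
        s = make_stream(["left"] * 30)
        assert entrance_bias(s) == {"left": 1.0, "middle": 0.0, "right": 0.0}

    def test_symmetric_thirds(self, make_stream):
        s = make_stream(["left"] * 10 + ["middle"] * 10 + ["right"] * 10)
        b = entrance_bias(s)
        assert b == pytest.approx({"left": 1 / 3, "middle": 1 / 3, "right": 1 / 3})

    def test_entries_beyond_window_ignored(self, make_stream):
        labels = ["left"] * 24 + ["middle"] * 3 + ["right"] * 3 + ["middle"] * 10
        b = entrance_bias(make_stream(labels))
        assert b == pytest.approx({"left": 0.8, "middle": 0.1, "right": 0.1})

    def test_empty_stream_errors(self, make_stream):
        with pytest.raises(ValidationError, match="no entries"):
            entrance_bias(make_stream([]))


class TestRewardLedger:
    def test_rewards_after_bias_window(self, make_stream):
        s = make_stream(["middle"] * 30 + ["left"] * 12)
        ledger = fr5_reward_ledger(s, "left")
        rewarded = ledger.loc[ledger["rewarded"], "entry_index"].tolist()
        assert rewarded == [35, 40]  # the 5th and 10th post-bias correct entries

    def test_no_correct_no_rewards(self, make_stream):
        s = make_stream(["middle"] * 50)
        assert fr5_reward_ledger(s, "left")["rewarded"].sum() == 0

    def test_fr1_rewards_every_post_bias_correct(self, make_stream):
        sched = TaskSchedule(fr=1)
        s = make_stream(["left"] * 40, sched)
        ledger = fr5_reward_ledger(s, "left")
        assert ledger["rewarded"].sum() == 10  # entries 31..40

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from(ENT), max_size=120),
           st.integers(min_value=1, max_value=7))
    def test_reward_conservation(self, labels, fr):
        sched = TaskSchedule(fr=fr)
        s = stream_from_labels(labels, sched)
        ledger = fr5_reward_ledger(s, "left")
        post_bias_correct = sum(
            1 for i, lab in enumerate(labels)
            if lab == "left" and i + 1 > sched.bias_window
        )
        assert ledger["rewarded"].sum() == post_bias_correct // fr


class TestEntriesToCriterion:
    def test_all_correct_floor_case(self, make_stream):
        r = entries_to_criterion(make_stream(["left"] * 30), "left")
        assert r.entries_to_criterion == 30 and not r.censored

    def test_inclusive_threshold_24_of_30(self, make_stream):
        s = make_stream(["middle"] * 6 + ["left"] * 24)
        r = entries_to_criterion(s, "left")
        assert r.entries_to_criterion == 30  # 24/30 = 0.8 passes at >=

    def test_23_of_30_does_not_pass_at_30(self, make_stream):
        s = make_stream(["middle"] * 7 + ["left"] * 24)
        r = entries_to_criterion(s, "left")
        assert r.entries_to_criterion == 31

    def test_never_correct_censored(self, make_stream):
        r = entries_to_criterion(make_stream(["middle"] * 200), "left")
        assert r.censored and r.entries_to_criterion is None
        assert r.total_entries == 200

    def test_short_stream_censored_not_exception(self, make_stream):
        r = entries_to_criterion(make_stream(["left"] * 10), "left")
        assert r.censored and r.total_entries == 10

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.sampled_from(ENT), max_size=150),
           st.integers(min_value=2, max_value=12),
           st.sampled_from([0.5, 0.7, 0.8, 1.0]))
    def test_agrees_with_brute_force_rescan(self, labels, window, threshold):
        sched = TaskSchedule(window=window, threshold=threshold)
        got = entries_to_criterion(stream_from_labels(labels, sched), "left")
        expected = brute_force_criterion(labels, "left", window, threshold)
        assert got.entries_to_criterion == expected
        assert got.censored == (expected is None)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(ENT), min_size=5, max_size=80),
           st.integers(min_value=1, max_value=20))
    def test_appending_incorrect_never_decreases(self, labels, extra):
        sched = TaskSchedule(window=10)
        base = entries_to_criterion(stream_from_labels(labels, sched), "left")
        longer = entries_to_criterion(
            stream_from_labels(labels + ["middle"] * extra, sched), "left")
        if base.entries_to_criterion is not None:
            assert longer.entries_to_criterion == base.entries_to_criterion
        elif longer.entries_to_criterion is not None:
            assert longer.entries_to_criterion > len(labels)

    def test_correcting_an_error_never_delays(self, make_stream):
        sched = TaskSchedule(window=10)
        rng = np.random.default_rng(4)
        for _ in range(50):
            labels = list(rng.choice(ENT, size=60))
            base = entries_to_criterion(make_stream(labels, sched), "left")
            wrong = [i for i, lab in enumerate(labels) if lab != "left"]
            if not wrong:
                continue
            i = int(rng.choice(wrong))
            flipped = list(labels)
            flipped[i] = "left"
            new = entries_to_criterion(make_stream(flipped, sched), "left")
            if base.entries_to_criterion is not None:
                assert new.entries_to_criterion is not None
                assert new.entries_to_criterion <= base.entries_to_criterion


class TestPhaseAndDaySplits:
    def test_split_phases_rezeros_rl(self, schedule, make_stream):
        import pandas as pd
        from phenocage.core import EntryStream
        t = np.array([100.0, schedule.rl_start_offset_s + 5.0])
        s = EntryStream("s1", pd.DataFrame({"t": t, "entrance": ["left", "right"]}),
                        schedule)
        dl, rl = split_phases(s)
        assert len(dl) == 1 and len(rl) == 1
        assert rl.t[0] == pytest.approx(5.0)

    def test_rl_day_partition(self, schedule, make_stream):
        s = make_stream(["left", "right"], schedule, dt=29 * 3600.0, t0=3600.0)
        d1, d2 = split_rl_days(s)
        assert len(d1) == 1 and len(d2) == 1

    def test_boundary_entry_goes_to_rl2(self, schedule, make_stream):
        s = make_stream(["left"], schedule, t0=RL_DAY_S)
        d1, d2 = split_rl_days(s)
        assert len(d1) == 0 and len(d2) == 1

    def test_all_early_entries_leave_rl2_empty(self, schedule, make_stream):
        s = make_stream(["left"] * 5, schedule, dt=3600.0)
        d1, d2 = split_rl_days(s)
        assert len(d1) == 5 and len(d2) == 0


class TestErrorClassification:
    def test_counting_example(self, make_stream):
        s = make_stream(["left", "left", "middle", "right", "right"])
        c = classify_rl_errors(s, "left", "right")
        assert (c.perseverative, c.neutral, c.correct) == (2, 1, 2)

    def test_all_new_target(self, make_stream):
        c = classify_rl_errors(make_stream(["right"] * 7), "left", "right")
        assert (c.perseverative, c.neutral) == (0, 0)

    def test_empty_substream(self, make_stream):
        c = classify_rl_errors(make_stream([]), "left", "right")
        assert (c.perseverative, c.neutral) == (0, 0)

    @pytest.mark.parametrize("prev,new", [
        ("left", "left"), ("middle", "right"), ("left", "middle"),
    ])
    def test_bad_targets_rejected(self, prev, new, make_stream):
        with pytest.raises(ConfigurationError):
            classify_rl_errors(make_stream(["left"]), prev, new)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(ENT), max_size=60))
    def test_partition_of_entries(self, labels):
        c = classify_rl_errors(stream_from_labels(labels), "left", "right")
        assert c.perseverative + c.neutral + c.correct == len(labels)


class TestActivityMeasures:
    def _track(self, xy, arena):
        import pandas as pd
        xy = np.asarray(xy, float)
        df = pd.DataFrame({
            "t": np.arange(len(xy), dtype=float),
            "nose_x": xy[:, 0], "nose_y": xy[:, 1],
            "cog_x": xy[:, 0], "cog_y": xy[:, 1],
        })
        return Track("s1", df, arena)

    def test_straight_3m_path(self, cage, make_stream):
        # 30 zig-zag steps of 10 cm inside the cage: 300 cm = 3 m
        pts = [(5.0 + 10.0 * (i % 2), 5.0) for i in range(31)]
        tr = self._track(pts, cage)
        m = activity_measures(make_stream(["left"]), tr, mask_zones=())
        assert m.total_distance_m == pytest.approx(3.0)

    def test_track_inside_shelter_masked_to_zero(self, cage, make_stream):
        pts = [(1.0, 28.0 + 0.1 * i) for i in range(10)]  # inside shelter corner
        tr = self._track(pts, cage)
        m = activity_measures(make_stream(["left"] * 3), tr)
        assert m.total_distance_m == pytest.approx(0.0)
        assert m.total_entries == 3

    def test_missing_track_distance_absent(self, make_stream):
        m = activity_measures(make_stream(["left"] * 4))
        assert m.total_distance_m is None and m.total_entries == 4

    def test_random_path_matches_pairwise_sum_oracle(self, cage, make_stream):
        rng = np.random.default_rng(11)
        pts = rng.uniform(5.0, 12.0, size=(100, 2))  # clear of both masks
        tr = self._track(pts, cage)
        m = activity_measures(make_stream(["left"]), tr)
        oracle = sum(
            float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(len(pts) - 1)
        ) / 100.0
        assert m.total_distance_m == pytest.approx(oracle)


class TestKMSurvival:
    def test_three_event_steps(self):
        res = {"g": [CriterionResult(f"s{i}", d, False, d)
                     for i, d in enumerate([30, 40, 50])]}
        sf = km_survival(res)["g"]
        lookup = dict(zip(sf["entries"], sf["fraction_remaining"]))
        assert lookup[30] == pytest.approx(2 / 3)
        assert lookup[40] == pytest.approx(1 / 3)
        assert lookup[50] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        res = {"g": [CriterionResult(f"s{i}", None, True, 300) for i in range(5)]}
        sf = km_survival(res)["g"]
        assert (sf["fraction_remaining"] == 1.0).all()

    def test_duplicate_event_times_single_step(self):
        res = {"g": [CriterionResult(f"s{i}", 40, False, 40) for i in range(4)]}
        sf = km_survival(res)["g"]
        assert (sf["entries"] == 40).sum() == 1
        lookup = dict(zip(sf["entries"], sf["fraction_remaining"]))
        assert lookup[40] == pytest.approx(0.0)

    def test_empty_group_named_in_error(self):
        with pytest.raises(ValidationError, match="grp_x"):
            km_survival({"grp_x": []})

    def test_censoring_shrinks_risk_set_without_step(self):
        # event at 30 (n=3 at risk), censor at 35, event at 50 (1 of 1 left)
        res = {"g": [CriterionResult("a", 30, False, 30),
                     CriterionResult("b", None, True, 35),
                     CriterionResult("c", 50, False, 50)]}
        sf = km_survival(res)["g"]
        lookup = dict(zip(sf["entries"], sf["fraction_remaining"]))
        assert lookup[30] == pytest.approx(2 / 3)
        assert lookup[50] == pytest.approx(0.0)
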