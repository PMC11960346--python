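"""Accelerometer preprocessing: non-wear, sleep scoring, classification,
daily summaries and the participant inclusion rule."""

import re

import numpy as np
import pandas as pd
import pytest

from coda24.accel import (
    ConfigError,
    CutPointConfig,
    DailySummary,
    GapError,
    MIN_WAKING_WEAR_MIN,
    classify_waking_epochs,
    detect_nonwear,
    participant_composition,
    process_participant,
    score_sleep,
    summarize_day,
)
from coda24.coda import CompositionError, closure


def nonwear_oracle(vm3, window=90, tol=2):
    """Regex scan: zero runs bridged by non-zero gaps of <= tol epochs."""
    s = "".join("0" if v == 0 else "1" for v in vm3)
    out = np.zeros(len(s), dtype=bool)
    for m in re.finditer(rf"0+(?:1{{1,{tol}}}(?=0)0+)*", s):
        if m.end() - m.start() >= window:
            out[m.start() : m.end()] = True
    return out


class TestNonwear:
    def test_all_zero_day_is_entirely_nonwear(self):
        assert detect_nonwear(np.zeros(1440)).all()

    def test_all_positive_day_is_entirely_wear(self):
        assert not detect_nonwear(np.ones(1440)).any()

    def test_spike_inside_long_zero_run_is_absorbed(self):
        vm3 = np.zeros(120)
        vm3[60] = 1.0  # 1-min spike inside a 120-min zero run
        flags = detect_nonwear(vm3, window_min=90, spike_tolerance_min=2)
        assert flags.all()

    def test_short_zero_run_stays_wear(self):
        vm3 = np.concatenate([np.ones(100), np.zeros(89), np.ones(100)])
        assert not detect_nonwear(vm3, window_min=90).any()

    def test_long_interruption_breaks_the_run(self):
        vm3 = np.concatenate([np.zeros(60), np.ones(3), np.zeros(60)])
        flags = detect_nonwear(vm3, window_min=90, spike_tolerance_min=2)
        assert not flags.any()  # two 60-min runs, not bridgeable

    def test_agrees_with_regex_oracle_on_random_days(self, rng):
        for _ in range(30):
            # sparse positives produce plenty of long zero runs
            vm3 = (rng.random(1440) < 0.03) * rng.integers(1, 100, 1440)
            got = detect_nonwear(vm3, window_min=90, spike_tolerance_min=2)
            assert np.array_equal(got, nonwear_oracle(vm3))

    def test_subminute_epochs_scale_the_window(self):
        # 30-s epochs: 90 min = 180 epochs
        flags = detect_nonwear(np.zeros(180), epoch_length_s=30, window_min=90)
        assert flags.all()
        assert not detect_nonwear(np.zeros(179), epoch_length_s=30, window_min=90).any()


def sleep_oracle(vm3, weights, threshold):
    """Brute-force windowed weighted sum with edge repetition."""
    half = len(weights) // 2
    padded = np.concatenate([np.full(half, vm3[0]), vm3, np.full(half, vm3[-1])])
    out = []
    for i in range(len(vm3)):
        out.append(float(np.dot(weights, padded[i : i + len(weights)])) < threshold)
    return np.array(out)


class TestSleepScore:
    WEIGHTS = np.array([0.04, 0.04, 0.2, 1.0, 0.2, 0.04, 0.04])

    def test_all_zero_segment_scores_sleep(self):
        assert score_sleep(np.zeros(60), self.WEIGHTS, threshold=100.0).all()

    def test_high_counts_score_wake(self):
        assert not score_sleep(np.full(60, 5000.0), self.WEIGHTS, 100.0).any()

    def test_matches_brute_force_windowed_sums(self, rng):
        vm3 = rng.integers(0, 200, 10).astype(float)
        got = score_sleep(vm3, self.WEIGHTS, threshold=100.0)
        assert np.array_equal(got, sleep_oracle(vm3, self.WEIGHTS, 100.0))

    def test_random_streams_match_oracle(self, rng):
        for _ in range(10):
            vm3 = rng.integers(0, 400, 500).astype(float)
            thr = float(rng.uniform(50, 300))
            assert np.array_equal(
                score_sleep(vm3, self.WEIGHTS, thr), sleep_oracle(vm3, self.WEIGHTS, thr)
            )

    def test_even_length_window_is_a_config_error(self):
        with pytest.raises(ConfigError, match="odd"):
            score_sleep(np.zeros(10), np.ones(4), 100.0)


class TestClassification:
    CFG = CutPointConfig(sb_upper=100.0, lpa_upper=500.0)

    def _labels(self, vm3, wear=True, sleep=False):
        n = np.size(vm3)
        return classify_waking_epochs(
            np.atleast_1d(np.asarray(vm3, dtype=float)),
            np.full(n, wear),
            np.full(n, sleep),
            self.CFG,
        )

    def test_zero_counts_awake_and_worn_is_sedentary(self):
        assert self._labels(0.0)[0] == "SB"

    @pytest.mark.parametrize(
        "vm3,expected",
        [(100.0, "SB"), (100.5, "LPA"), (500.0, "LPA"), (501.0, "MVPA")],
    )
    def test_cutpoint_boundaries_are_inclusive_upper(self, vm3, expected):
        assert self._labels(vm3)[0] == expected

    def test_nonwear_dominates_sleep_and_counts(self):
        assert self._labels(5000.0, wear=False, sleep=True)[0] == "NONWEAR"

    def test_sleep_dominates_cutpoints_when_worn(self):
        assert self._labels(5000.0, wear=True, sleep=True)[0] == "TST"


class TestDailySummary:
    def _summary(self, n_sb, n_other_label="TST", epoch_s=60):
        per_day = 86400 // epoch_s
        labels = np.array(["SB"] * n_sb + [n_other_label] * (per_day - n_sb))
        return summarize_day(labels, epoch_s, "P1", pd.Timestamp("2023-05-01").date())

    def test_minute_totals_follow_label_counts(self):
        day = self._summary(600)
        assert day.sb_min == 600.0
        assert day.tst_min == 840.0

    def test_ten_hour_boundary_is_inclusive(self):
        assert self._summary(600).is_valid  # exactly 600 waking-wear min
        assert not self._summary(599).is_valid

    def test_sleep_does_not_count_toward_waking_wear(self):
        day = self._summary(300, "TST")
        assert day.waking_wear_min == 300.0
        assert not day.is_valid

    def test_label_partition_totals_1440_minutes(self, rng):
        labels = rng.choice(["TST", "SB", "LPA", "MVPA", "NONWEAR"], 1440)
        day = summarize_day(labels, 60, "P1", pd.Timestamp("2023-05-01").date())
        nonwear = 1440 - day.tst_min - day.waking_wear_min
        assert np.isclose(day.tst_min + day.sb_min + day.lpa_min + day.mvpa_min + nonwear, 1440.0)

    def test_permuting_epochs_leaves_totals_unchanged(self, rng):
        labels = rng.choice(["TST", "SB", "LPA", "MVPA", "NONWEAR"], 1440)
        a = summarize_day(labels, 60, "P", pd.Timestamp("2023-05-01").date())
        b = summarize_day(rng.permutation(labels), 60, "P", pd.Timestamp("2023-05-01").date())
        assert a.minutes().tolist() == b.minutes().tolist()


def make_day(valid=True, minutes=(340.0, 830.0, 155.0, 115.0), day=0):
    wake = sum(minutes[1:])
    return DailySummary(
        "P1",
        (pd.Timestamp("2023-05-01") + pd.Timedelta(days=day)).date(),
        *minutes,
        waking_wear_min=wake if valid else 400.0,
        is_valid=valid,
    )


class TestParticipantComposition:
    def test_three_valid_days_excluded_four_included(self):
        days = [make_day(valid=True, day=d) for d in range(3)]
        assert participant_composition(days, min_valid_days=4) is None
        days.append(make_day(valid=True, day=3))
        assert participant_composition(days, min_valid_days=4) is not None

    def test_identical_days_average_to_their_closure(self):
        days = [make_day(day=d) for d in range(4)]
        comp = participant_composition(days)
        assert np.allclose(comp, closure([340.0, 830.0, 155.0, 115.0]))

    def test_invalid_days_are_ignored_in_the_average(self):
        days = [make_day(day=d) for d in range(4)]
        days.append(make_day(valid=False, minutes=(0.0, 400.0, 0.0, 0.0), day=4))
        assert np.allclose(participant_composition(days), closure([340, 830, 155, 115]))

    def test_removing_a_valid_day_never_rescues_an_excluded_participant(self):
        days = [make_day(day=d) for d in range(3)]
        assert participant_composition(days) is None
        assert participant_composition(days[:-1]) is None

    def test_all_zero_means_raise_degenerate_error(self):
        days = [make_day(minutes=(0.0, 0.0, 0.0, 0.0), day=d) for d in range(4)]
        for d in days:
            assert d.is_valid  # validity was forced by the helper
        with pytest.raises(CompositionError, match="degenerate"):
            participant_composition(days)


class TestProcessParticipant:
    def _stream(self, vm3, start="2023-05-01"):
        ts = pd.date_range(start, periods=len(vm3), freq="60s")
        return pd.DataFrame({"participant_id": "P1", "timestamp": ts, "vm3": vm3})

    def test_gap_in_timestamps_is_reported(self):
        df = self._stream(np.ones(200))
        df = pd.concat([df.iloc[:100], df.iloc[101:]], ignore_index=True)
        with pytest.raises(GapError, match="gap"):
            process_participant(df, CutPointConfig())

    def test_partial_days_are_dropped(self):
        # 1.5 days starting at midnight -> only the first full day kept
        df = self._stream(np.full(2160, 200.0))
        days = process_participant(df, CutPointConfig())
        assert len(days) == 1
        assert days[0].sb_min == 1440.0
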