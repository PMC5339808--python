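"""Wear detection, wake/sleep splitting, re-epoching and cut-point tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actibout.preprocess import (SLEEP, UNKNOWN, WAKE, CountsSeries,
                                 DiaryRecord, cutpoint_summary, detect_nonwear,
                                 read_counts, read_diary, reepoch,
                                 split_states, vector_magnitude, write_counts,
                                 write_diary)

T0 = pd.Timestamp("2024-01-01 00:00:00")


def make_series(counts, epoch=1, **kw):
    return CountsSeries(start_time=T0, epoch=epoch,
                        counts=np.asarray(counts, dtype=float), **kw)


class TestVectorMagnitude:
    def test_345_triangle(self):
        assert vector_magnitude([3.0], [4.0], [0.0])[0] == pytest.approx(5.0)

    def test_zero_and_unit(self):
        assert vector_magnitude([0.0], [0.0], [0.0])[0] == 0.0
        assert vector_magnitude([1.0], [1.0], [1.0])[0] == pytest.approx(
            1.7320508, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            vector_magnitude([1.0, 2.0], [1.0], [1.0])


class TestNonwear:
    def test_exactly_180_minutes_flagged(self):
        s = make_series([1.0] + [0.0] * 10_800 + [1.0])
        wear = detect_nonwear(s)
        assert not wear[1:10_801].any()
        assert wear[0] and wear[-1]

    def test_one_second_short_not_flagged(self):
        s = make_series([1.0] + [0.0] * 10_799 + [1.0])
        assert detect_nonwear(s).all()

    def test_interrupted_zeros_not_flagged(self):
        # two 90-minute zero runs split by a single nonzero second
        counts = [0.0] * 5400 + [2.0] + [0.0] * 5400
        s = make_series(counts)
        assert detect_nonwear(s).all()

    def test_diary_interval_masks(self):
        s = make_series([1.0] * 100)
        diary = DiaryRecord(nonwear_intervals=[
            (T0 + pd.Timedelta(seconds=10), T0 + pd.Timedelta(seconds=20))])
        wear = detect_nonwear(s, diary)
        assert not wear[10:20].any()
        assert wear[:10].all() and wear[20:].all()

    def test_masking_never_alters_counts(self):
        s = make_series([0.0] * 20_000)
        before = s.counts.copy()
        detect_nonwear(s)
        assert np.array_equal(s.counts, before)


class TestSplitStates:
    def _series_hours(self, hours):
        return make_series(np.ones(hours * 3600))

    def test_ratio_three_not_flagged(self):
        # 18 h wake, 6 h sleep -> ratio exactly 3, strict inequality spares it
        s = self._series_hours(24)
        diary = DiaryRecord(days={"2024-01-01": (
            T0 + pd.Timedelta(hours=18), T0 + pd.Timedelta(hours=24))})
        out, rep = split_states(s, diary)
        assert rep["wake_sleep_ratio"] == pytest.approx(3.0)
        assert not rep["insufficient_sleep"]
        assert (out.state == SLEEP).sum() == 6 * 3600

    def test_ratio_above_three_flagged(self):
        s = self._series_hours(25)
        diary = DiaryRecord(days={
            "2024-01-01": (T0 + pd.Timedelta(hours=19),
                           T0 + pd.Timedelta(hours=25))})
        _, rep = split_states(s, diary)
        assert rep["wake_sleep_ratio"] == pytest.approx(19 / 6, rel=1e-9)
        assert rep["insufficient_sleep"]

    def test_all_wake_subject(self):
        s = self._series_hours(2)
        diary = DiaryRecord(days={"2024-01-01": (
            T0 + pd.Timedelta(hours=30), T0 + pd.Timedelta(hours=38))})
        out, rep = split_states(s, diary)
        assert (out.state == WAKE).all()
        assert rep["insufficient_sleep"]  # no worn sleep at all

    def test_missing_diary_days_excluded_by_default(self):
        s = make_series(np.ones(2 * 86_400))  # two days, diary covers one
        diary = DiaryRecord(days={"2024-01-01": (
            T0 + pd.Timedelta(hours=22), T0 + pd.Timedelta(hours=30))})
        out, _ = split_states(s, diary)
        # the second day beyond the sleep window is uncovered -> unworn
        day2 = out.state[30 * 3600:]
        assert (day2 == UNKNOWN).all()
        assert not out.wear[30 * 3600:].any()

    def test_inverted_diary_times_rejected(self):
        with pytest.raises(ValueError):
            DiaryRecord(days={"2024-01-01": (
                T0 + pd.Timedelta(hours=8), T0 + pd.Timedelta(hours=7))})

    def test_wake_plus_sleep_conserves_worn_time(self):
        s = self._series_hours(24)
        diary = DiaryRecord(days={"2024-01-01": (
            T0 + pd.Timedelta(hours=16), T0 + pd.Timedelta(hours=24))})
        out, rep = split_states(s, diary)
        assert rep["worn_wake_s"] + rep["worn_sleep_s"] == int(out.wear.sum())


class TestReepoch:
    def test_sixty_ones_sum_to_sixty(self):
        out = reepoch(make_series(np.ones(60)), 60)
        assert len(out) == 1 and out.counts[0] == 60.0

    def test_identity(self):
        s = make_series([1.0, 2.0, 3.0])
        out = reepoch(s, 1)
        assert np.array_equal(out.counts, s.counts)

    def test_trailing_remainder_dropped(self):
        out = reepoch(make_series(np.ones(61)), 60)
        assert len(out) == 1 and out.counts[0] == 60.0

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            reepoch(make_series(np.ones(120), epoch=7), 60)

    def test_window_with_nonwear_is_nonwear(self):
        wear = np.ones(120, dtype=bool)
        wear[5] = False
        out = reepoch(make_series(np.ones(120), wear=wear), 60)
        assert not out.wear[0] and out.wear[1]

    @given(st.integers(min_value=60, max_value=400), st.integers(0, 2**31 - 1))
    def test_total_counts_conserved_over_complete_windows(self, n, seed):
        c = np.random.default_rng(seed).integers(0, 50, size=n).astype(float)
        out = reepoch(make_series(c), 60)
        m = (n // 60) * 60
        assert out.counts.sum() == pytest.approx(c[:m].sum())


class TestCutpoints:
    def _cpm(self, values, state=None):
        kw = {}
        if state is not None:
            kw["state"] = state
        return make_series(values, epoch=60, **kw)

    def test_simple_fractions(self):
        rep = cutpoint_summary(self._cpm([50.0, 150.0, 2500.0]))
        assert rep["sb_fraction"] == pytest.approx(1 / 3)
        assert rep["mvpa_fraction"] == pytest.approx(1 / 3)

    def test_boundary_rules(self):
        # 100 cpm is sedentary (inclusive); 2019 cpm is not MVPA (exclusive)
        rep = cutpoint_summary(self._cpm([100.0, 2019.0]))
        assert rep["sb_fraction"] == pytest.approx(0.5)
        assert rep["mvpa_fraction"] == 0.0

    def test_all_zero_day(self):
        rep = cutpoint_summary(self._cpm([0.0] * 10))
        assert rep["sb_fraction"] == 1.0 and rep["mvpa_fraction"] == 0.0

    def test_no_worn_wake_minutes_is_error(self):
        s = self._cpm([1.0, 2.0], state=np.array([SLEEP, SLEEP], dtype=np.int8))
        with pytest.raises(ValueError):
            cutpoint_summary(s)


class TestIO:
    def test_counts_roundtrip(self, tmp_path):
        s = make_series([0.0, 1.5, 3.0])
        path = tmp_path / "counts.csv"
        write_counts(s, path)
        back = read_counts(path)
        assert back.epoch == 1
        assert np.allclose(back.counts, s.counts)
        assert back.start_time == s.start_time

    def test_axis_counts_get_vector_magnitude(self, tmp_path):
        path = tmp_path / "axes.csv"
        pd.DataFrame({
            "timestamp": pd.date_range(T0, periods=2, freq="1s"),
            "axis1": [3, 0], "axis2": [4, 0], "axis3": [0, 0],
        }).to_csv(path, index=False)
        s = read_counts(path)
        assert np.allclose(s.counts, [5.0, 0.0])

    def test_diary_roundtrip(self, tmp_path):
        diary = DiaryRecord(
            days={"2024-01-01": (T0 + pd.Timedelta(hours=22),
                                 T0 + pd.Timedelta(hours=30))},
            nonwear_intervals=[(T0 + pd.Timedelta(hours=1),
                                T0 + pd.Timedelta(hours=2))])
        path = tmp_path / "diary.csv"
        write_diary(diary, path)
        back = read_diary(path)
        assert back.days.keys() == diary.days.keys()
        assert back.nonwear_intervals == diary.nonwear_intervals
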