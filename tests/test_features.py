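"""Engineered features: rolling windows, diary features, schemas, causality."""

import numpy as np
import pandas as pd
import pytest

from hypowatch import features as feat
from hypowatch import labeling as lab
from hypowatch import segmentation as seg
from hypowatch import timeline as tlmod
from hypowatch.timeline import CHANNELS, ParticipantTimeline

T0 = pd.Timestamp("2024-03-01 00:00")


def _series(values, start=T0):
    return pd.Series(values, index=pd.date_range(start, periods=len(values), freq="min"), dtype=float)


class TestRollingWindows:
    def test_constant_series_mean_is_constant(self):
        out = feat.rolling_mean(_series([70.0] * 120), 10)
        assert (out == 70.0).all()

    def test_trailing_mean_hand_computed(self):
        out = feat.rolling_mean(_series([60.0, 70.0, 80.0] + [np.nan] * 7), 10)
        assert out.iloc[0] == 60.0 and out.iloc[1] == 65.0 and out.iloc[2] == 70.0

    def test_all_missing_window_is_missing(self):
        vals = [70.0] + [np.nan] * 30
        out = feat.rolling_mean(_series(vals), 10)
        assert np.isnan(out.iloc[15])

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            feat.rolling_mean(_series([1.0]), 20)
        with pytest.raises(ValueError):
            feat.rolling_sum(_series([1.0]), 10)

    def test_burst_persists_for_window_then_drops(self):
        vals = np.zeros(120)
        vals[10] = 100.0
        out = feat.rolling_sum(_series(vals), 30)
        assert (out.iloc[10:40] == 100.0).all()
        assert (out.iloc[40:] == 0.0).all()

    def test_two_bursts_in_one_window_add(self):
        vals = np.zeros(60)
        vals[5] = 50.0
        vals[20] = 50.0
        out = feat.rolling_sum(_series(vals), 30)
        assert out.iloc[25] == 100.0

    def test_missing_steps_treated_as_zero(self):
        vals = [np.nan] * 30 + [10.0] + [np.nan] * 29
        out = feat.rolling_sum(_series(vals), 30)
        assert out.iloc[29] == 0.0 and out.iloc[30] == 10.0


def _tl_with_hrv(obs: dict[int, float], n=120) -> ParticipantTimeline:
    idx = pd.date_range(T0, periods=n, freq="min")
    data = pd.DataFrame({c: np.nan for c in CHANNELS}, index=idx)
    flags = pd.DataFrame("missing", index=idx, columns=list(CHANNELS))
    for minute, value in obs.items():
        data.iloc[minute, data.columns.get_loc("hrv")] = value
        flags.iloc[minute, flags.columns.get_loc("hrv")] = "observed"
    tl = ParticipantTimeline("P01", data, flags)
    return tlmod.forward_fill_limited(tl, "hrv", 15)


class TestHrvFeatures:
    def test_delta_is_difference_of_consecutive_observations(self):
        tl = _tl_with_hrv({0: 40.0, 30: 55.0})
        _, delta = feat.hrv_features(tl)
        assert np.isnan(delta.iloc[29])
        assert (delta.iloc[30:] == 15.0).all()

    def test_delta_missing_before_second_observation(self):
        tl = _tl_with_hrv({10: 40.0})
        _, delta = feat.hrv_features(tl)
        assert delta.isna().all()

    def test_equal_observations_give_zero_delta(self):
        tl = _tl_with_hrv({0: 40.0, 20: 40.0})
        _, delta = feat.hrv_features(tl)
        assert delta.iloc[20] == 0.0

    def test_last_value_respects_fill_limit(self):
        tl = _tl_with_hrv({0: 40.0})
        last, _ = feat.hrv_features(tl)
        assert (last.iloc[:16] == 40.0).all() and last.iloc[16:].isna().all()


class TestTimeOfDay:
    @pytest.mark.parametrize(
        "hhmm,expected",
        [("06:00", (1.0, 0.0)), ("00:00", (0.0, 1.0)), ("18:00", (-1.0, 0.0)), ("12:00", (0.0, -1.0))],
    )
    def test_cardinal_hours(self, hhmm, expected):
        idx = pd.DatetimeIndex([f"2024-03-01 {hhmm}"])
        s, c = feat.encode_time_of_day(idx)
        assert s.iloc[0] == pytest.approx(expected[0], abs=1e-12)
        assert c.iloc[0] == pytest.approx(expected[1], abs=1e-12)

    def test_unit_circle_identity_and_fractional_hours(self):
        idx = pd.date_range("2024-03-01", periods=1440, freq="min")
        s, c = feat.encode_time_of_day(idx)
        np.testing.assert_allclose(s**2 + c**2, 1.0, atol=1e-12)
        assert s.iloc[30] != s.iloc[0]  # minute resolution, not integer hours


class TestDiaryFeatures:
    def test_time_since_meal_floor_and_cap(self):
        meals = [pd.Timestamp("2024-03-01 12:00")]
        idx = pd.DatetimeIndex(
            ["2024-03-01 12:59", "2024-03-01 14:30", "2024-03-01 11:00", "2024-03-02 04:00"]
        )
        out = feat.time_since_last_meal(meals, idx, cap_hours=12)
        assert out.iloc[0] == 0 and out.iloc[1] == 2
        assert np.isnan(out.iloc[2])  # before the first meal
        assert out.iloc[3] == 12  # capped (16 h later)

    @pytest.mark.parametrize(
        "hours_after,expected",
        [(0.5, 1.0), (1.5, 0.75), (2.5, 0.5), (3.5, 0.25), (4.0, 0.25), (5.0, 0.0)],
    )
    def test_insulin_on_board_schedule(self, hours_after, expected):
        dose = pd.Timestamp("2024-03-01 08:00")
        idx = pd.DatetimeIndex([dose + pd.Timedelta(hours=hours_after)])
        assert feat.insulin_on_board([dose], idx).iloc[0] == expected

    def test_new_dose_resets_the_clock(self):
        doses = [pd.Timestamp("2024-03-01 08:00"), pd.Timestamp("2024-03-01 11:00")]
        idx = pd.DatetimeIndex(["2024-03-01 11:30"])
        assert feat.insulin_on_board(doses, idx).iloc[0] == 1.0

    def test_no_doses_means_zero(self):
        idx = pd.date_range("2024-03-01", periods=5, freq="h")
        assert (feat.insulin_on_board([], idx) == 0.0).all()


@pytest.fixture(scope="module")
def matrices(participant, assembled):
    labels, events = lab.label_hypoglycemia(assembled)
    segments = seg.assign_segments(participant.diary, participant.participant_id)
    seg.mark_event_segments(segments, events)
    day = feat.build_feature_matrix(assembled, participant.diary, segments, labels, "day")
    night = feat.build_feature_matrix(assembled, participant.diary, segments, labels, "night")
    return day, night


class TestSchemas:
    def test_waking_matrix_has_13_features(self, matrices):
        day, _ = matrices
        cols = [c for c in day.columns if c not in ("label", "segment_id")]
        assert len(cols) == 13 and "bos_last" not in cols and "rr_last" not in cols

    def test_sleeping_matrix_has_10_features(self, matrices):
        _, night = matrices
        cols = [c for c in night.columns if c not in ("label", "segment_id")]
        assert len(cols) == 10 and "steps_rs30" not in cols and "energy_rs60" not in cols

    def test_union_of_schemas_is_15_variables(self):
        assert len(set(feat.DAY_FEATURES) | set(feat.NIGHT_FEATURES)) == 15

    def test_missing_meal_records_drop_the_meal_feature(self, participant, assembled):
        labels, events = lab.label_hypoglycemia(assembled)
        segments = seg.assign_segments(participant.diary, participant.participant_id)
        day = feat.build_feature_matrix(
            assembled, participant.diary, segments, labels, "day", include_meal=False
        )
        cols = [c for c in day.columns if c not in ("label", "segment_id")]
        assert len(cols) == 12 and "time_since_meal" not in cols

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            feat.schema_for("dusk")

    def test_rows_keep_timestamps_and_segment_ids(self, matrices):
        day, _ = matrices
        assert isinstance(day.index, pd.DatetimeIndex)
        assert day["segment_id"].str.contains("_day").all()


class TestCausality:
    def test_future_perturbation_never_changes_past_features(self, participant, assembled):
        """Rewrite every channel after a cut point; features before it must not move."""
        diary = participant.diary
        cut = assembled.index[len(assembled.index) // 2]
        base = feat.compute_features(assembled, diary)

        tampered = assembled.copy()
        future = tampered.index > cut
        tampered.data.loc[future, :] = 999.0
        # also tamper future diary entries
        diary2 = diary.copy()
        diary2.loc[diary2["timestamp"] > cut, "timestamp"] += pd.Timedelta(hours=2)
        after = feat.compute_features(tampered, diary2)

        past = base.index <= cut
        pd.testing.assert_frame_equal(base.loc[past], after.loc[past])
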