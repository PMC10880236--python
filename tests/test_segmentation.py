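"""Non-wear truncation, waking-day windows, and the validity/inclusion gates."""

import datetime as dt

import pandas as pd
import pytest

from uprightkit.segmentation import (
    DayValidity,
    filter_valid_days,
    include_participant,
    segment_waking_days,
    truncate_at_first_nonwear,
)

from conftest import DAY_VALID, PARTIAL_DAY, multiday, stream


class TestTruncation:
    def test_data_after_first_nonwear_removed(self):
        series = stream([("standing", 60), ("sedentary", 600), ("nonwear", 3600), ("standing", 60)])
        out = truncate_at_first_nonwear(series)
        assert len(out) == 2 and "nonwear" not in set(out.frame["activity"])

    def test_no_nonwear_is_identity(self):
        series = stream([("standing", 60), ("sedentary", 600)])
        out = truncate_at_first_nonwear(series)
        pd.testing.assert_frame_equal(out.frame, series.frame)

    def test_leading_nonwear_gives_empty_series(self):
        series = stream([("nonwear", 3600), ("standing", 60)])
        assert len(truncate_at_first_nonwear(series)) == 0


class TestWakingDayWindows:
    def test_window_runs_from_first_qualifying_upright_to_last_noncrossing_event(self):
        series = multiday("P", [("20:00", PARTIAL_DAY), ("06:30", DAY_VALID)])
        days = segment_waking_days(series)
        assert len(days) == 1
        day = days[0]
        assert day.date == dt.date(2017, 5, 2)
        assert day.wake_start == pd.Timestamp("2017-05-02 06:30:00")
        # DAY_VALID is 37 200 s of contiguous events from 06:30
        assert day.day_end == pd.Timestamp("2017-05-02 06:30:00") + pd.Timedelta(seconds=37200)
        assert day.waking_wear_h == pytest.approx(37200 / 3600)

    def test_first_recorded_day_is_excluded(self):
        series = multiday("P", [("09:00", DAY_VALID), ("06:30", DAY_VALID)])
        days = segment_waking_days(series)
        assert [d.date for d in days] == [dt.date(2017, 5, 2)]

    def test_midnight_crossing_event_is_dropped(self):
        series = multiday("P", [("20:00", PARTIAL_DAY), ("06:30", DAY_VALID), ("07:00", DAY_VALID)])
        day = segment_waking_days(series)[0]
        # the overnight sedentary filler crosses midnight and must not appear
        assert (day.frame["start"] + pd.to_timedelta(day.frame["duration_s"], unit="s")).max() <= pd.Timestamp("2017-05-03")
        assert day.day_end == pd.Timestamp("2017-05-02 06:30:00") + pd.Timedelta(seconds=37200)

    def test_upright_spanning_anchor_does_not_open_the_day(self):
        """An upright event starting before 03:00 cannot anchor the window."""
        events = [("standing", 1200), ("sedentary", 13800), ("standing", 600)] + DAY_VALID
        series = multiday("P", [("20:00", PARTIAL_DAY), ("02:50", events)])
        day = segment_waking_days(series)[0]
        # 02:50 + 1200 s spans 03:00 but starts earlier; 02:50+1200+13800 = 07:00
        assert day.wake_start == pd.Timestamp("2017-05-02 07:00:00")

    def test_short_upright_after_anchor_does_not_open_the_day(self):
        events = [("standing", 8), ("sedentary", 3592), ("standing", 600)] + DAY_VALID
        series = multiday("P", [("20:00", PARTIAL_DAY), ("06:00", events)])
        day = segment_waking_days(series)[0]
        assert day.wake_start == pd.Timestamp("2017-05-02 07:00:00")

    def test_day_without_qualifying_upright_yields_no_window(self):
        # only upright activity before 03:00 on 2017-05-03
        series = multiday(
            "P",
            [("20:00", PARTIAL_DAY), ("06:30", DAY_VALID), ("00:30", [("standing", 600), ("sedentary", 7200)])],
        )
        assert [d.date for d in segment_waking_days(series)] == [dt.date(2017, 5, 2)]

    def test_recording_end_without_crossing_event_closes_at_last_event(self):
        short_day = [("standing", 1200), ("sedentary", 3600), ("stepping", 600, 900)]
        series = multiday("P", [("20:00", PARTIAL_DAY), ("06:30", short_day)])
        day = segment_waking_days(series)[0]
        assert day.day_end == pd.Timestamp("2017-05-02 06:30:00") + pd.Timedelta(seconds=5400)

    def test_window_containment_and_no_day_leakage(self, small_cohort):
        for series in small_cohort.series:
            truncated = truncate_at_first_nonwear(series)
            days = segment_waking_days(truncated)
            seen = set()
            for day in days:
                starts = day.frame["start"]
                ends = starts + pd.to_timedelta(day.frame["duration_s"], unit="s")
                assert (starts >= day.wake_start).all() and (ends <= day.day_end).all()
                keys = set(zip(starts, day.frame["duration_s"]))
                assert not (keys & seen)
                seen |= keys

    def test_configured_wake_time_recovered_to_the_second(self):
        from uprightkit.simulate import SimConfig, generate_cohort

        cfg = SimConfig(n_participants=1, wake_time_h=(6.5, 6.5), sleep_time_h=(23.0, 23.0), effects=())
        cohort = generate_cohort(cfg, 5)
        days = segment_waking_days(cohort.series[0])
        assert len(days) == cfg.n_days
        for day in days:
            assert day.wake_start.time() == dt.time(6, 30)
            assert day.day_end <= pd.Timestamp(dt.datetime.combine(day.date, dt.time(23, 0)))


class TestValidityGates:
    def test_hand_counted_verdicts(self, hand_participants):
        validities = filter_valid_days(segment_waking_days(hand_participants["A"]))
        assert [v.valid for v in validities] == [True, False, False]
        assert validities[1].wear_ok and not validities[1].events_ok  # 3 events, 11 h
        assert not validities[2].wear_ok and validities[2].events_ok  # 4 events, 9.5 h

    def test_exactly_three_upright_events_invalid(self, hand_participants):
        v = filter_valid_days(segment_waking_days(hand_participants["A"]))[1]
        assert v.n_upright_events == 3 and not v.valid

    def test_exactly_ten_hours_valid(self, hand_participants):
        validities = filter_valid_days(segment_waking_days(hand_participants["B"]))
        boundary = validities[5]  # the exact-10 h day
        assert boundary.day.waking_wear_h == pytest.approx(10.0)
        assert boundary.valid


class TestInclusion:
    @staticmethod
    def _stub(n_valid, n_invalid=0):
        mk = lambda ok: DayValidity(day=None, wear_ok=ok, events_ok=ok, n_upright_events=0)
        return [mk(True)] * n_valid + [mk(False)] * n_invalid

    @pytest.mark.parametrize("n_valid, expected", [(5, False), (6, True), (7, True)])
    def test_six_valid_day_boundary(self, n_valid, expected):
        assert include_participant(self._stub(n_valid, 2)) is expected

    def test_hand_counted_inclusion(self, hand_participants):
        decisions = {
            pid: include_participant(filter_valid_days(segment_waking_days(series)))
            for pid, series in hand_participants.items()
        }
        assert decisions == {"A": False, "B": True}
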