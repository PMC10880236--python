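"""Burstiness statistic, stepping metrics, and daily/person summaries."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uprightkit.composition import build_posture_events
from uprightkit.metrics import (
    InterEventSeries,
    burstiness,
    daily_burstiness_pair,
    daily_summary,
    person_summary,
    step_weighted_cadence,
)
from uprightkit.segmentation import segment_waking_days

from conftest import multiday, stream


def reference_burstiness(gaps, n):
    """Direct evaluation of the n-corrected burstiness equation.

    Deliberately coded apart from the package path (statistics module, plain
    floats) to act as an independent oracle.
    """
    r = statistics.pstdev(gaps) / statistics.fmean(gaps)
    return (math.sqrt(n + 1) * r - math.sqrt(n - 1)) / (
        (math.sqrt(n + 1) - 2) * r + math.sqrt(n - 1)
    )


class TestBurstiness:
    @pytest.mark.parametrize("n", [3, 4, 10, 53])
    def test_equal_gaps_give_exact_minimum(self, n):
        series = InterEventSeries(n_events=n, gaps=(30.0,) * (n - 1))
        assert burstiness(series) == -1.0

    def test_frozen_example(self):
        series = InterEventSeries(n_events=5, gaps=(2.0, 2.0, 2.0, 10.0))
        assert burstiness(series) == pytest.approx(0.05077716922772137, abs=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(3, 60))
            gaps = np.abs(rng.lognormal(1.0, 1.2, n - 1)) + 1e-9
            got = burstiness(InterEventSeries(n_events=n, gaps=tuple(gaps)))
            assert got == pytest.approx(reference_burstiness(list(gaps), n), abs=1e-12)

    def test_undefined_cases_are_nan(self):
        assert math.isnan(burstiness(InterEventSeries(n_events=2, gaps=(5.0,))))
        assert math.isnan(burstiness(InterEventSeries(n_events=4, gaps=(0.0, 0.0, 0.0))))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2, max_size=49)
    )
    def test_bounded_on_nonnegative_gaps(self, gaps):
        series = InterEventSeries(n_events=len(gaps) + 1, gaps=tuple(gaps))
        b = burstiness(series)
        if not math.isnan(b):
            assert -1.0 <= b <= 1.0 + 1e-12

    @pytest.mark.parametrize("n", [4, 10, 30])
    def test_strictly_increasing_in_dispersion(self, n):
        from uprightkit.metrics import burstiness_coefficient

        rs = np.linspace(1e-6, math.sqrt(n - 2), 50)
        values = [burstiness_coefficient(r, n) for r in rs]
        assert all(b2 > b1 for b1, b2 in zip(values, values[1:]))

    def test_sample_sd_convention_flag(self):
        series = InterEventSeries(n_events=5, gaps=(2.0, 2.0, 2.0, 10.0))
        pop = burstiness(series, sd_convention="population")
        samp = burstiness(series, sd_convention="sample")
        assert samp > pop  # ddof=1 inflates r

    def test_interval_count_convention_flag(self):
        series = InterEventSeries(n_events=6, gaps=(1.0, 2.0, 3.0, 4.0, 5.0))
        assert burstiness(series, n_convention="intervals") == pytest.approx(
            reference_burstiness([1, 2, 3, 4, 5], 5), abs=1e-12
        )


class TestDailyBurstinessPair:
    def test_types_are_separated(self):
        # upright gaps all equal (1800 s) while upright durations vary
        events = [("sedentary", 1800)]
        for dur in (60, 300, 600, 900):
            events += [("standing", dur), ("sedentary", 1800)]
        posture = build_posture_events(stream(events).frame)
        b_up, b_sed = daily_burstiness_pair(posture)
        assert b_up == -1.0
        assert b_sed > -1.0

    def test_sedentary_gaps_are_upright_durations(self):
        events = [("sedentary", 1800)]
        for dur in (60, 300, 600, 900):
            events += [("standing", dur), ("sedentary", 1800)]
        posture = build_posture_events(stream(events).frame)
        sed_gaps = InterEventSeries.from_events(posture.sedentary).gaps
        assert sed_gaps == pytest.approx((1.0, 5.0, 10.0, 15.0))


class TestCadence:
    def test_single_event_identity(self):
        events = pd.DataFrame({"duration_s": [60.0], "steps": [100]})
        assert step_weighted_cadence(events) == pytest.approx(100.0)

    def test_step_weighting(self):
        events = pd.DataFrame({"duration_s": [60.0, 10.0], "steps": [100, 10]})
        assert step_weighted_cadence(events) == pytest.approx((100 * 100 + 10 * 60) / 110)

    def test_ten_step_minimum_excludes_event(self):
        events = pd.DataFrame({"duration_s": [60.0, 8.0], "steps": [100, 8]})
        assert step_weighted_cadence(events) == pytest.approx(100.0)

    def test_no_qualifying_events_is_nan(self):
        events = pd.DataFrame({"duration_s": [8.0], "steps": [8]})
        assert math.isnan(step_weighted_cadence(events))

    def test_weighted_mean_between_extremes(self):
        rng = np.random.default_rng(3)
        events = pd.DataFrame(
            {"duration_s": rng.uniform(10, 120, 50), "steps": rng.integers(10, 200, 50)}
        )
        cadences = events["steps"] / (events["duration_s"] / 60)
        assert cadences.min() <= step_weighted_cadence(events) <= cadences.max()


HAND_DAY = [
    ("standing", 1200),
    ("sedentary", 10800),
    ("stepping", 600, 900),  # 90 steps/min
    ("sedentary", 10800),
    ("standing", 600),
    ("stepping", 60, 8),  # below the 10-step cadence minimum
    ("sedentary", 10800),
    ("stepping", 1200, 2400),  # 120 steps/min
]


class TestDailySummary:
    @pytest.fixture()
    def hand_day(self):
        series = multiday("P", [("20:00", [("standing", 600), ("sedentary", 3600)]), ("06:30", HAND_DAY)])
        day = segment_waking_days(series)[0]
        return day, build_posture_events(day)

    def test_hand_tally(self, hand_day):
        day, posture = hand_day
        m = daily_summary(day, posture)
        assert m.n_upright_events == 4
        assert m.n_stepping_events == 3
        assert m.upright_h == pytest.approx((1200 + 600 + 600 + 60 + 1200) / 3600)
        assert m.standing_h == pytest.approx(1800 / 3600)
        assert m.stepping_h == pytest.approx(1860 / 3600)
        assert m.daily_steps == 900 + 8 + 2400  # the 8-step event still counts here
        assert m.step_weighted_cadence == pytest.approx((900 * 90 + 2400 * 120) / 3300)
        assert m.waking_wear_h == pytest.approx(sum(d for _, d, *_ in HAND_DAY) / 3600)

    def test_upright_hours_conserved(self, hand_day):
        day, posture = hand_day
        m = daily_summary(day, posture)
        assert m.upright_h == pytest.approx(m.standing_h + m.stepping_h)
        assert m.upright_h == pytest.approx(sum(e.duration_min for e in posture.upright) / 60)

    def test_zero_stepping_day(self):
        events = [("standing", 1200), ("sedentary", 10800)] * 4
        series = multiday("P", [("20:00", [("standing", 600), ("sedentary", 3600)]), ("06:30", events)])
        day = segment_waking_days(series)[0]
        m = daily_summary(day, build_posture_events(day))
        assert m.stepping_h == 0.0 and m.daily_steps == 0
        assert math.isnan(m.step_weighted_cadence)


class TestPersonSummary:
    @staticmethod
    def _metrics(day_tuple):
        day, posture = day_tuple
        return daily_summary(day, posture)

    def test_identical_days_idempotent(self):
        series = multiday(
            "P", [("20:00", [("standing", 600), ("sedentary", 3600)])] + [("06:30", HAND_DAY)] * 3
        )
        daily = [daily_summary(d, build_posture_events(d)) for d in segment_waking_days(series)]
        out = person_summary("P", daily)
        assert out["n_valid_days"] == 3
        assert out["daily_steps"] == pytest.approx(daily[0].daily_steps)
        assert out["upright_events_n"] == pytest.approx(daily[0].n_upright_events)

    def test_nan_metrics_averaged_over_defined_days(self):
        series = multiday(
            "P",
            [("20:00", [("standing", 600), ("sedentary", 3600)])]
            + [("06:30", HAND_DAY), ("06:30", [("standing", 1200), ("sedentary", 10800)] * 4)],
        )
        daily = [daily_summary(d, build_posture_events(d)) for d in segment_waking_days(series)]
        assert math.isnan(daily[1].step_weighted_cadence)
        out = person_summary("P", daily)
        assert out["step_weighted_cadence"] == pytest.approx(daily[0].step_weighted_cadence)
        assert out["n_days_step_weighted_cadence"] == 1

    def test_no_days_raises(self):
        with pytest.raises(ValueError):
            person_summary("P", [])
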