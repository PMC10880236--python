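"""Shared fixtures: hand-built event streams and session-scoped synthetic cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from uprightkit.events import EventSeries
from uprightkit.pipeline import PipelineConfig, summarise_participant
from uprightkit.simulate import SimConfig, generate_cohort


def stream(events, start="2017-05-02 06:30:00", pid="P0001") -> EventSeries:
    """Build a contiguous EventSeries from (activity, duration_s[, steps]) tuples."""
    t = pd.Timestamp(start)
    rows = []
    for item in events:
        activity, dur = item[0], float(item[1])
        steps = int(item[2]) if len(item) > 2 else 0
        rows.append({"start": t, "duration_s": dur, "activity": activity, "steps": steps})
        t += pd.Timedelta(seconds=dur)
    return EventSeries(pid, pd.DataFrame(rows))


def multiday(pid, day_plans, first_date="2017-05-01"):
    """Stitch per-day plans into one contiguous multi-day series.

    ``day_plans`` is a list of ``(wake "HH:MM", events)`` tuples, one per
    consecutive calendar date starting at ``first_date`` (the first is the
    partial attachment day).  Nights are filled with a single sedentary event
    crossing midnight, as a 24 h-worn monitor would record sleep.
    """
    d0 = pd.Timestamp(first_date)
    frames = []
    prev_end = None
    for i, (wake, events) in enumerate(day_plans):
        start = pd.Timestamp(f"{(d0 + pd.Timedelta(days=i)).date()} {wake}")
        if prev_end is not None:
            night = (start - prev_end).total_seconds()
            frames.append(
                pd.DataFrame(
                    [{"start": prev_end, "duration_s": night, "activity": "sedentary", "steps": 0}]
                )
            )
        s = stream(events, start=start, pid=pid)
        frames.append(s.frame)
        prev_end = s.ends.iloc[-1]
    return EventSeries(pid, pd.concat(frames, ignore_index=True))


# hand-countable day plans for the cleaning-gate fixtures ---------------------

#: 4 upright events, 37 200 s (10.33 h) of wear -> valid
DAY_VALID = [
    ("standing", 1200), ("sedentary", 10800), ("stepping", 1200, 2000),
    ("sedentary", 10800), ("standing", 1200), ("sedentary", 10800),
    ("stepping", 1200, 2000),
]
#: exactly 3 upright events, 39 600 s (11 h) -> invalid (needs > 3)
DAY_TOO_FEW_EVENTS = [
    ("standing", 1200), ("sedentary", 18000), ("stepping", 1200, 2000),
    ("sedentary", 18000), ("standing", 1200),
]
#: 4 upright events but 34 200 s (9.5 h) -> invalid (needs >= 10 h)
DAY_TOO_SHORT = [
    ("standing", 1200), ("sedentary", 10000), ("standing", 1200),
    ("sedentary", 10000), ("stepping", 1200, 2000), ("sedentary", 9400),
    ("standing", 1200),
]
#: exactly 10 h of wear, 4 upright events -> valid (boundary)
DAY_EXACT_10H = [
    ("standing", 1200), ("sedentary", 10400), ("stepping", 1200, 2000),
    ("sedentary", 10400), ("standing", 1200), ("sedentary", 10400),
    ("stepping", 1200, 2000),
]
PARTIAL_DAY = [("standing", 600), ("sedentary", 3600)]


@pytest.fixture(scope="session")
def hand_participants():
    """Two participants with hand-counted gate outcomes.

    A: partial day + [valid, too-few-events, too-short] -> 1 valid day, excluded.
    B: partial day + 5 valid + 1 exact-10h valid + 1 invalid -> 6 valid, included.
    """
    a = multiday("A", [("20:00", PARTIAL_DAY)] + [
        ("06:30", DAY_VALID), ("06:30", DAY_TOO_FEW_EVENTS), ("06:30", DAY_TOO_SHORT),
    ])
    b = multiday("B", [("20:00", PARTIAL_DAY)] + [("06:30", DAY_VALID)] * 5 + [
        ("06:30", DAY_EXACT_10H), ("06:30", DAY_TOO_SHORT),
    ])
    return {"A": a, "B": b}


# session-scoped synthetic cohorts --------------------------------------------

SMALL_COHORT_SEED = 1701


@pytest.fixture(scope="session")
def small_cohort():
    """Four participants, default generator, for structural/property checks."""
    return generate_cohort(SimConfig(n_participants=4), SMALL_COHORT_SEED)


CALIBRATION_SEED = 424242


@pytest.fixture(scope="session")
def calibration_summaries():
    """120 participants with covariate effects disabled, run through the pipeline.

    Used for the self-consistency checks of the generator's descriptive
    anchors; effects are off so the anchors are the clean expectations.
    """
    cohort = generate_cohort(SimConfig(n_participants=120, effects=()), CALIBRATION_SEED)
    config = PipelineConfig(run_models=False)
    rows = []
    for series in cohort.series:
        result = summarise_participant(series, config)
        if result["included"]:
            rows.append(result["summary"])
    return pd.DataFrame(rows), cohort
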