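"""Waking-day segmentation and valid-day / inclusion filters.

A 24 h-worn posture monitor records sleep as long sedentary events, so waking
time has to be cut out of the stream heuristically.  The convention
implemented here keys on an anchor in the early morning (03:00 by default, an
approximate population mid-sleep point): each calendar day's waking window
runs from the start of the first upright event of at least 10 s beginning at
or after the anchor, to the end of the last event that does not cross the
following midnight (the crossing event itself — typically the overnight
sedentary bout — is dropped).  The first recorded calendar day is a partial
attachment day and never yields a window.

A day is *valid* when its window spans at least ``min_wear_h`` hours and
contains more than three upright events of at least 10 s; a participant is
included when they contribute at least ``min_valid_days`` valid days.  All
thresholds are parameters so sensitivity runs can move them.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import pandas as pd

from .events import UPRIGHT_ACTIVITIES, EventSeries

__all__ = [
    "WakingDay",
    "DayValidity",
    "truncate_at_first_nonwear",
    "segment_waking_days",
    "filter_valid_days",
    "include_participant",
]

log = logging.getLogger(__name__)

DEFAULT_ANCHOR = dt.time(3, 0)
DEFAULT_MIN_WEAR_H = 10.0
DEFAULT_MIN_UPRIGHT_EVENTS = 4  # "> 3" as a count floor
DEFAULT_MIN_VALID_DAYS = 6
DEFAULT_EVENT_FLOOR_S = 10.0


@dataclass
class WakingDay:
    """One participant-day waking window and the events wholly inside it.

    The window is half-open ``[wake_start, day_end)``; every contained event
    starts at or after ``wake_start`` and ends by ``day_end``, and none
    crosses the midnight after ``wake_start``.
    """

    participant_id: str
    date: dt.date
    wake_start: pd.Timestamp
    day_end: pd.Timestamp
    frame: pd.DataFrame

    @property
    def waking_wear_h(self) -> float:
        return (self.day_end - self.wake_start).total_seconds() / 3600.0

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class DayValidity:
    """Validity verdict for one waking day under the two day-level gates."""

    day: WakingDay
    wear_ok: bool
    events_ok: bool
    n_upright_events: int

    @property
    def valid(self) -> bool:
        return self.wear_ok and self.events_ok


def truncate_at_first_nonwear(series: EventSeries) -> EventSeries:
    """Keep only the prefix strictly before the first non-wear event.

    Participants are instructed not to reattach the device, so anything after
    the first non-wear bout is untrustworthy and removed.  A series that opens
    with non-wear truncates to an empty series (logged).
    """
    mask = (series.frame["activity"] == "nonwear").to_numpy()
    if not mask.any():
        return series
    cut = int(mask.argmax())
    if cut == 0:
        log.warning("participant %s: series begins with non-wear; no usable data", series.participant_id)
    return EventSeries(series.participant_id, series.frame.iloc[:cut].copy(), series.dialect)


def segment_waking_days(
    series: EventSeries,
    anchor: dt.time = DEFAULT_ANCHOR,
    min_upright_s: float = DEFAULT_EVENT_FLOOR_S,
) -> list[WakingDay]:
    """Cut a (non-wear-truncated) series into per-date waking windows.

    For every calendar date after the first recorded date: the window opens at
    the start of the first standing/stepping event of at least
    ``min_upright_s`` seconds beginning at or after ``anchor`` on that date,
    and closes at the end of the last event that does not cross the following
    midnight.  Dates with no qualifying upright event yield no window.
    """
    if series.empty:
        return []
    frame = series.frame
    starts = frame["start"]
    ends = series.ends
    first_date = starts.iloc[0].date()
    dates = sorted(set(starts.dt.date))

    days: list[WakingDay] = []
    for date in dates:
        if date == first_date:
            continue  # partial attachment day
        anchor_ts = pd.Timestamp(dt.datetime.combine(date, anchor))
        midnight = pd.Timestamp(dt.datetime.combine(date + dt.timedelta(days=1), dt.time.min))
        qualifying = (
            frame["activity"].isin(UPRIGHT_ACTIVITIES)
            & (frame["duration_s"] >= min_upright_s)
            & (starts >= anchor_ts)
            & (starts < midnight)
        )
        if not qualifying.any():
            log.info("participant %s, %s: no qualifying upright event after %s", series.participant_id, date, anchor)
            continue
        wake_start = starts[qualifying].iloc[0]
        in_day = (starts >= wake_start) & (ends <= midnight)
        if not in_day.any():
            continue
        day_end = ends[in_day].max()
        contained = (starts >= wake_start) & (ends <= day_end)
        days.append(
            WakingDay(
                participant_id=series.participant_id,
                date=date,
                wake_start=wake_start,
                day_end=day_end,
                frame=frame[contained].reset_index(drop=True),
            )
        )
    return days


def filter_valid_days(
    days: list[WakingDay],
    min_wear_h: float = DEFAULT_MIN_WEAR_H,
    min_upright_events: int = DEFAULT_MIN_UPRIGHT_EVENTS,
    floor_s: float = DEFAULT_EVENT_FLOOR_S,
) -> list[DayValidity]:
    """Apply the wear-time and upright-event-count gates to each day.

    Upright events are counted after upright-event construction (contiguous
    standing/stepping runs with the ``floor_s`` minimum), not as raw rows.
    """
    from .composition import build_posture_events  # local import to avoid a cycle

    out = []
    for day in days:
        n_upright = len(build_posture_events(day, floor_s=floor_s).upright)
        out.append(
            DayValidity(
                day=day,
                wear_ok=day.waking_wear_h >= min_wear_h,
                events_ok=n_upright >= min_upright_events,
                n_upright_events=n_upright,
            )
        )
    return out


def include_participant(
    validities: list[DayValidity], min_valid_days: int = DEFAULT_MIN_VALID_DAYS
) -> bool:
    """Participant-level inclusion: at least ``min_valid_days`` valid days."""
    return sum(v.valid for v in validities) >= min_valid_days
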