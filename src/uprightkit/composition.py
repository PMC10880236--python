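"""Upright-event construction and composition metrics.

An *upright event* (sitting interruption, sedentary break) is the interval
between a sit-to-stand transition and the next stand-to-sit transition: a
maximal run of consecutive standing/stepping events.  Sedentary events are the
mirror image — maximal runs of non-upright events between two upright events.
Runs shorter than the 10 s classification floor are discarded outright (not
merged into a neighbour, which would silently relabel posture time); their
duration is tracked so that per-day time conservation can be asserted:

    upright + sedentary + discarded = waking wear time.

Each upright event is characterised by its duration, the split of that
duration into standing and stepping, the number of stepping events it
contains, and its step count; the percentage of its duration spent stepping
is the *stepping proportion*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .events import UPRIGHT_ACTIVITIES
from .segmentation import DEFAULT_EVENT_FLOOR_S, WakingDay

__all__ = [
    "UprightEvent",
    "SedentaryEvent",
    "PostureEvents",
    "CompositionMetrics",
    "build_posture_events",
    "build_upright_events",
    "compose_event",
    "person_mean_composition",
]


@dataclass
class UprightEvent:
    """A contiguous standing/stepping run between sedentary events."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_min: float
    standing_min: float
    stepping_min: float
    n_stepping_events: int
    step_count: int
    sub_events: pd.DataFrame


@dataclass
class SedentaryEvent:
    """A contiguous sedentary run between upright events."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_min: float


@dataclass
class PostureEvents:
    """Upright and sedentary events of one waking day, plus discarded time."""

    upright: list[UprightEvent]
    sedentary: list[SedentaryEvent]
    discarded_s: float


@dataclass(frozen=True)
class CompositionMetrics:
    """Per-upright-event composition: duration, % stepping, stepping events, steps."""

    duration_min: float
    stepping_proportion_pct: float
    n_stepping_events: int
    step_count: int


def build_posture_events(
    day: WakingDay | pd.DataFrame, floor_s: float = DEFAULT_EVENT_FLOOR_S
) -> PostureEvents:
    """Group a day's classified events into upright and sedentary events.

    ``other`` (and any stray non-wear) rows sit on the sedentary side of the
    partition: an unknown behaviour never creates or extends an upright event.
    """
    frame = day.frame if isinstance(day, WakingDay) else day
    if frame.empty:
        return PostureEvents([], [], 0.0)

    is_up = frame["activity"].isin(UPRIGHT_ACTIVITIES).to_numpy()
    run_id = np.concatenate([[0], np.cumsum(is_up[1:] != is_up[:-1])])

    upright: list[UprightEvent] = []
    sedentary: list[SedentaryEvent] = []
    discarded_s = 0.0
    for rid in np.unique(run_id):
        sub = frame.iloc[run_id == rid]
        dur_s = float(sub["duration_s"].sum())
        start = sub["start"].iloc[0]
        end = sub["start"].iloc[-1] + pd.Timedelta(seconds=float(sub["duration_s"].iloc[-1]))
        if dur_s < floor_s:
            discarded_s += dur_s
            continue
        if is_up[np.flatnonzero(run_id == rid)[0]]:
            stepping = sub["activity"] == "stepping"
            stepping_s = float(sub.loc[stepping, "duration_s"].sum())
            upright.append(
                UprightEvent(
                    start=start,
                    end=end,
                    duration_min=dur_s / 60.0,
                    standing_min=(dur_s - stepping_s) / 60.0,
                    stepping_min=stepping_s / 60.0,
                    n_stepping_events=int(stepping.sum()),
                    step_count=int(sub.loc[stepping, "steps"].sum()),
                    sub_events=sub.reset_index(drop=True),
                )
            )
        else:
            sedentary.append(SedentaryEvent(start=start, end=end, duration_min=dur_s / 60.0))
    return PostureEvents(upright, sedentary, discarded_s)


def build_upright_events(
    day: WakingDay | pd.DataFrame, floor_s: float = DEFAULT_EVENT_FLOOR_S
) -> list[UprightEvent]:
    """Convenience wrapper returning only the upright events of a day."""
    return build_posture_events(day, floor_s=floor_s).upright


def compose_event(event: UprightEvent) -> CompositionMetrics:
    """Composition metrics of a single upright event."""
    if event.duration_min <= 0:
        raise ValueError("upright event has zero duration")
    return CompositionMetrics(
        duration_min=event.duration_min,
        stepping_proportion_pct=100.0 * event.stepping_min / event.duration_min,
        n_stepping_events=event.n_stepping_events,
        step_count=event.step_count,
    )


#: Column names of the person-level composition means.
COMPOSITION_COLUMNS = (
    "upright_event_duration_min",
    "stepping_proportion_pct",
    "stepping_events_per_upright_event",
    "steps_per_upright_event",
)


def person_mean_composition(
    events_by_day: Iterable[list[UprightEvent]],
    method: Literal["pooled", "daily"] = "pooled",
) -> dict[str, float]:
    """Per-person mean composition over the upright events of valid days.

    ``pooled`` (default) averages over every upright event across days, so a
    day with more events carries more weight; ``daily`` averages within each
    day first and then across days.
    """
    day_tables = []
    for events in events_by_day:
        if not events:
            continue
        metrics = [compose_event(e) for e in events]
        day_tables.append(
            pd.DataFrame(
                {
                    "upright_event_duration_min": [m.duration_min for m in metrics],
                    "stepping_proportion_pct": [m.stepping_proportion_pct for m in metrics],
                    "stepping_events_per_upright_event": [float(m.n_stepping_events) for m in metrics],
                    "steps_per_upright_event": [float(m.step_count) for m in metrics],
                }
            )
        )
    if not day_tables:
        raise ValueError("no upright events: person composition undefined")
    if method == "pooled":
        pooled = pd.concat(day_tables, ignore_index=True)
        return pooled.mean().to_dict()
    if method == "daily":
        daily = pd.DataFrame([t.mean() for t in day_tables])
        return daily.mean().to_dict()
    raise ValueError(f"unknown composition-mean method {method!r}")
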