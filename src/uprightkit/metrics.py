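"""Daily summary metrics, stepping metrics, and the burstiness statistic.

Burstiness measures how unevenly events of one type are spread over a waking
day.  For a day with ``n`` events of a type and inter-event times
``tau_1 … tau_{n-1}`` (end of one event to start of the next event of the
same type, never spanning the overnight gap), let ``r = sigma / <tau>`` be
the coefficient of variation of the gaps.  The finite-size-corrected
statistic is

    B_n = (sqrt(n+1) * r - sqrt(n-1)) / ((sqrt(n+1) - 2) * r + sqrt(n-1))

which equals -1 for perfectly regular gaps (sigma = 0) and approaches +1 as
the gaps become maximally clustered.  ``sigma`` is the population standard
deviation of the ``n - 1`` gaps and ``n`` counts events, not gaps; both
conventions are switchable for comparison with other codebases.

Because inter-event times of one event type are, in an alternating stream,
exactly the durations of the opposite type, sedentary-event burstiness reads
as the variability of upright-event durations and vice versa.

The step-weighted cadence weights each stepping event's cadence
(steps / minute) by its step count, restricted to events of at least ten
steps — shorter flurries cannot carry a reliable cadence, though their steps
still count toward the daily step total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import PostureEvents, SedentaryEvent, UprightEvent
from .segmentation import WakingDay

__all__ = [
    "InterEventSeries",
    "DailyMetrics",
    "burstiness",
    "burstiness_coefficient",
    "daily_burstiness_pair",
    "step_weighted_cadence",
    "daily_summary",
    "person_summary",
]

MIN_EVENTS_FOR_BURSTINESS = 3
DEFAULT_CADENCE_MIN_STEPS = 10


@dataclass(frozen=True)
class InterEventSeries:
    """Inter-event times of one event type within one waking day.

    ``n_events`` counts the events themselves; ``gaps`` holds the
    ``n_events - 1`` end-to-next-start intervals in minutes.
    """

    n_events: int
    gaps: tuple[float, ...]

    def __post_init__(self):
        if len(self.gaps) != max(self.n_events - 1, 0):
            raise ValueError(
                f"{self.n_events} events require {self.n_events - 1} gaps, got {len(self.gaps)}"
            )
        if any(g < 0 for g in self.gaps):
            raise ValueError("negative inter-event time")

    @classmethod
    def from_events(cls, events: Sequence[UprightEvent | SedentaryEvent]) -> "InterEventSeries":
        gaps = tuple(
            (nxt.start - prev.end).total_seconds() / 60.0 for prev, nxt in zip(events, events[1:])
        )
        return cls(n_events=len(events), gaps=gaps)

    @property
    def mean_gap(self) -> float:
        return float(np.mean(self.gaps)) if self.gaps else math.nan

    def sd_gap(self, ddof: int = 0) -> float:
        return float(np.std(self.gaps, ddof=ddof)) if len(self.gaps) > ddof else math.nan


def burstiness_coefficient(r: float, n: int) -> float:
    """Evaluate the n-corrected burstiness formula at coefficient of variation ``r``."""
    sp, sm = math.sqrt(n + 1), math.sqrt(n - 1)
    return (sp * r - sm) / ((sp - 2.0) * r + sm)


def burstiness(
    series: InterEventSeries,
    sd_convention: Literal["population", "sample"] = "population",
    n_convention: Literal["events", "intervals"] = "events",
) -> float:
    """Day-level burstiness of one event type; NaN when undefined.

    Undefined when fewer than three events occurred or when the mean gap is
    zero (all-zero gaps).  A zero standard deviation returns exactly -1.
    ``n_convention="intervals"`` plugs the number of gaps rather than the
    number of events into the correction terms, for comparison with codebases
    that count intervals.
    """
    n = series.n_events if n_convention == "events" else series.n_events - 1
    if series.n_events < MIN_EVENTS_FOR_BURSTINESS or n < MIN_EVENTS_FOR_BURSTINESS - (
        n_convention == "intervals"
    ):
        return math.nan
    mean = series.mean_gap
    if not mean > 0:
        return math.nan
    sd = series.sd_gap(ddof=0 if sd_convention == "population" else 1)
    if sd == 0:
        return -1.0
    return burstiness_coefficient(sd / mean, n)


def daily_burstiness_pair(
    posture: PostureEvents,
    sd_convention: Literal["population", "sample"] = "population",
    n_convention: Literal["events", "intervals"] = "events",
) -> tuple[float, float]:
    """(upright, sedentary) burstiness of one waking day.

    Each type's inter-event times are measured end-to-next-start within the
    waking window only, so the overnight gap never enters.
    """
    kwargs = dict(sd_convention=sd_convention, n_convention=n_convention)
    b_up = burstiness(InterEventSeries.from_events(posture.upright), **kwargs)
    b_sed = burstiness(InterEventSeries.from_events(posture.sedentary), **kwargs)
    return b_up, b_sed


def step_weighted_cadence(
    stepping_events: pd.DataFrame, min_steps: int = DEFAULT_CADENCE_MIN_STEPS
) -> float:
    """Step-count-weighted mean cadence (steps/min) over qualifying events.

    ``stepping_events`` holds one row per stepping event with ``duration_s``
    and ``steps``.  Events below ``min_steps`` are excluded here (they still
    count toward the daily step total); NaN when no event qualifies.
    """
    ok = stepping_events[
        (stepping_events["steps"] >= min_steps) & (stepping_events["duration_s"] > 0)
    ]
    if ok.empty:
        return math.nan
    cadence = ok["steps"] / (ok["duration_s"] / 60.0)
    return float(np.average(cadence, weights=ok["steps"]))


@dataclass
class DailyMetrics:
    """The per-day metric vector (averaged per person downstream)."""

    date: object
    waking_wear_h: float
    n_upright_events: int
    n_stepping_events: int
    upright_h: float
    standing_h: float
    stepping_h: float
    daily_steps: int
    step_weighted_cadence: float
    mean_stepping_event_duration_s: float
    mean_steps_per_stepping_event: float
    burstiness_upright: float
    burstiness_sedentary: float


#: DailyMetrics fields averaged into the person summary.
_MEAN_FIELDS = (
    "waking_wear_h",
    "n_upright_events",
    "n_stepping_events",
    "upright_h",
    "standing_h",
    "stepping_h",
    "daily_steps",
    "step_weighted_cadence",
    "mean_stepping_event_duration_s",
    "mean_steps_per_stepping_event",
    "burstiness_upright",
    "burstiness_sedentary",
)

#: Person-summary column names for the daily means (Table-style labels).
PERSON_METRIC_COLUMNS = {
    "n_upright_events": "upright_events_n",
    "n_stepping_events": "stepping_events_n",
    "daily_steps": "daily_steps",
    "waking_wear_h": "waking_wear_h",
    "upright_h": "upright_h",
    "standing_h": "standing_h",
    "stepping_h": "stepping_h",
    "step_weighted_cadence": "step_weighted_cadence",
    "mean_stepping_event_duration_s": "stepping_event_duration_s",
    "mean_steps_per_stepping_event": "steps_per_stepping_event",
    "burstiness_upright": "burstiness_upright",
    "burstiness_sedentary": "burstiness_sedentary",
}


def daily_summary(
    day: WakingDay,
    posture: PostureEvents,
    cadence_min_steps: int = DEFAULT_CADENCE_MIN_STEPS,
    sd_convention: Literal["population", "sample"] = "population",
    n_convention: Literal["events", "intervals"] = "events",
) -> DailyMetrics:
    """All daily metrics for one valid waking day.

    Stepping-event counts, durations and the daily step total are taken over
    every classified stepping event in the window (including those inside
    runs discarded by the 10 s floor); upright/standing/stepping hours come
    from the constructed upright events, so that
    ``upright_h = standing_h + stepping_h`` holds by construction.
    """
    stepping = day.frame[day.frame["activity"] == "stepping"]
    upright_min = sum(e.duration_min for e in posture.upright)
    standing_min = sum(e.standing_min for e in posture.upright)
    stepping_min = sum(e.stepping_min for e in posture.upright)
    b_up, b_sed = daily_burstiness_pair(
        posture, sd_convention=sd_convention, n_convention=n_convention
    )
    return DailyMetrics(
        date=day.date,
        waking_wear_h=day.waking_wear_h,
        n_upright_events=len(posture.upright),
        n_stepping_events=len(stepping),
        upright_h=upright_min / 60.0,
        standing_h=standing_min / 60.0,
        stepping_h=stepping_min / 60.0,
        daily_steps=int(stepping["steps"].sum()),
        step_weighted_cadence=step_weighted_cadence(stepping, min_steps=cadence_min_steps),
        mean_stepping_event_duration_s=float(stepping["duration_s"].mean()) if len(stepping) else math.nan,
        mean_steps_per_stepping_event=float(stepping["steps"].mean()) if len(stepping) else math.nan,
        burstiness_upright=b_up,
        burstiness_sedentary=b_sed,
    )


def person_summary(
    participant_id: str,
    daily: Sequence[DailyMetrics],
    covariates: Mapping[str, object] | None = None,
    composition: Mapping[str, float] | None = None,
) -> dict[str, object]:
    """Unweighted mean over valid days of every daily metric.

    Metrics undefined on some days (e.g. burstiness on a day with too few
    events) are averaged over the days where they are defined; no imputation.
    The count of defined days per metric is recorded as ``n_days_<metric>``
    only when it differs from the number of valid days.
    """
    if not daily:
        raise ValueError(f"participant {participant_id}: no valid days to summarise")
    out: dict[str, object] = {"participant_id": participant_id, "n_valid_days": len(daily)}
    table = pd.DataFrame([{f.name: getattr(d, f.name) for f in fields(DailyMetrics)} for d in daily])
    for field_name in _MEAN_FIELDS:
        col = table[field_name]
        name = PERSON_METRIC_COLUMNS[field_name]
        out[name] = float(col.mean())  # pandas mean skips NaN days
        n_defined = int(col.notna().sum())
        if n_defined != len(daily):
            out[f"n_days_{name}"] = n_defined
    if composition:
        out.update({k: float(v) for k, v in composition.items()})
    if covariates:
        out.update(dict(covariates))
    return out
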