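"""Posture event tables: reading, validation, writing.

Thigh-worn activity monitors of the activPAL class export their postural
classification as an *event table*: one row per contiguous interval of a
single behaviour (sitting/lying, standing, stepping, or non-wear), carrying a
start timestamp, a duration in seconds, an activity code, and — for stepping
rows — a step count.  This module normalises such tables into the package's
internal event model and enforces the structural invariants the downstream
stages rely on: events are sorted, non-overlapping, half-open intervals
``[start, start + duration)``; steps are carried only by stepping events; gaps
between consecutive events are tolerated only at non-wear boundaries.

Timestamps are naive local clock time throughout.  The day-cutting rules
downstream are anchored at wall-clock times, so no timezone or DST handling is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITIES",
    "UPRIGHT_ACTIVITIES",
    "DIALECTS",
    "Event",
    "EventSeries",
    "ValidationReport",
    "EventTableError",
    "EventValidationError",
    "read_event_table",
    "read_cohort_table",
    "write_event_table",
    "write_cohort_table",
    "validate_series",
]

#: Internal activity vocabulary.  ``other`` collects any source code that the
#: dialect does not map; for upright-event construction it is treated as
#: sedentary (conservative: an unknown behaviour never creates an upright
#: event).
ACTIVITIES = ("sedentary", "standing", "stepping", "nonwear", "other")
UPRIGHT_ACTIVITIES = frozenset({"standing", "stepping"})

#: Source-code dialects.  The shipped default mirrors the common numeric
#: coding of CREA-classified output (0 sitting/lying, 1 standing, 2 stepping,
#: 4 non-wear); anything unmapped becomes ``other``.
DIALECTS: dict[str, dict[int, str]] = {
    "activpal_crea": {0: "sedentary", 1: "standing", 2: "stepping", 4: "nonwear"},
}

#: Code used when writing an activity the dialect has no code for.
_OTHER_CODE = 9

CANONICAL_COLUMNS = ["participant_id", "start", "duration_s", "activity_code", "steps"]

_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


class EventTableError(ValueError):
    """A posture event table could not be parsed."""


class EventValidationError(EventTableError):
    """A parsed event table violates the event-model invariants."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(f"row {i}: {rule} ({msg})" for i, rule, msg in report.issues[:5])
        more = "" if len(report.issues) <= 5 else f" (+{len(report.issues) - 5} more)"
        super().__init__(f"event series failed validation: {lines}{more}")


class Event(NamedTuple):
    """One classified posture/stepping interval.

    The interval is half-open, ``[start, start + duration_s)``.  ``steps`` is
    zero for every activity except ``stepping``.
    """

    start: pd.Timestamp
    duration_s: float
    activity: str
    steps: int

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=float(self.duration_s))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_series`: ``ok`` iff ``issues`` is empty."""

    issues: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, row: int, rule: str, message: str) -> None:
        self.issues.append((row, rule, message))

    def rules(self) -> set[str]:
        return {rule for _, rule, _ in self.issues}


@dataclass
class EventSeries:
    """An ordered stream of posture events for one participant.

    The events live in ``frame`` with columns ``start`` (datetime64),
    ``duration_s`` (float seconds), ``activity`` (one of :data:`ACTIVITIES`)
    and ``steps`` (int).  ``dialect`` records which source code-mapping
    produced the activity labels.
    """

    participant_id: str
    frame: pd.DataFrame
    dialect: str = "activpal_crea"

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def empty(self) -> bool:
        return self.frame.empty

    @property
    def starts(self) -> pd.Series:
        return self.frame["start"]

    @property
    def ends(self) -> pd.Series:
        return self.frame["start"] + pd.to_timedelta(self.frame["duration_s"], unit="s")

    @property
    def events(self) -> list[Event]:
        return list(self.iter_events())

    def iter_events(self) -> Iterator[Event]:
        for row in self.frame.itertuples(index=False):
            yield Event(row.start, float(row.duration_s), row.activity, int(row.steps))

    @classmethod
    def from_events(
        cls, participant_id: str, events: list[Event], dialect: str = "activpal_crea"
    ) -> "EventSeries":
        frame = pd.DataFrame(
            {
                "start": [pd.Timestamp(e.start) for e in events],
                "duration_s": [float(e.duration_s) for e in events],
                "activity": [e.activity for e in events],
                "steps": [int(e.steps) for e in events],
            }
        )
        return cls(participant_id, frame, dialect)


def _dialect_map(dialect: str | Mapping[int, str]) -> dict[int, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise EventTableError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    return dict(dialect)


def _inverse_dialect(mapping: Mapping[int, str]) -> dict[str, int]:
    inv: dict[str, int] = {}
    for code, act in sorted(mapping.items()):
        inv.setdefault(act, int(code))
    inv.setdefault("other", _OTHER_CODE)
    return inv


def _normalise_frame(raw: pd.DataFrame, mapping: Mapping[int, str], source: str) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise EventTableError(f"{source}: missing columns {missing}")

    start = pd.to_datetime(raw["start"], errors="coerce")
    if start.isna().any():
        row = int(np.flatnonzero(start.isna().to_numpy())[0])
        raise EventTableError(f"{source}: malformed timestamp at row {row}: {raw['start'].iloc[row]!r}")

    duration = pd.to_numeric(raw["duration_s"], errors="coerce")
    if duration.isna().any():
        row = int(np.flatnonzero(duration.isna().to_numpy())[0])
        raise EventTableError(f"{source}: malformed duration at row {row}: {raw['duration_s'].iloc[row]!r}")
    if (duration < 0).any():
        row = int(np.flatnonzero((duration < 0).to_numpy())[0])
        raise EventTableError(f"{source}: negative duration at row {row}: {duration.iloc[row]}")

    codes = pd.to_numeric(raw["activity_code"], errors="coerce")
    if codes.isna().any():
        row = int(np.flatnonzero(codes.isna().to_numpy())[0])
        raise EventTableError(f"{source}: malformed activity code at row {row}")
    activity = codes.astype(int).map(dict(mapping)).fillna("other")

    steps = pd.to_numeric(raw["steps"], errors="coerce").fillna(0).astype(int)

    return pd.DataFrame(
        {"start": start, "duration_s": duration.astype(float), "activity": activity, "steps": steps}
    )


def read_cohort_table(
    path, dialect: str | Mapping[int, str] = "activpal_crea", strict: bool = True
) -> dict[str, EventSeries]:
    """Read a (possibly multi-participant) event CSV into per-participant series.

    Expected columns: ``participant_id``, ``start`` (ISO-8601), ``duration_s``,
    ``activity_code``, ``steps``.  Activity codes are mapped through the
    dialect; unmapped codes become ``other``.  In strict mode any validation
    issue raises :class:`EventValidationError`.
    """
    mapping = _dialect_map(dialect)
    dialect_name = dialect if isinstance(dialect, str) else "custom"
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EventTableError(f"{path}: empty event table")
    if raw.empty:
        raise EventTableError(f"{path}: empty event table")

    out: dict[str, EventSeries] = {}
    for pid, grp in raw.groupby("participant_id", sort=False):
        frame = _normalise_frame(grp.reset_index(drop=True), mapping, str(path))
        series = EventSeries(str(pid), frame, dialect_name)
        report = validate_series(series)
        if strict and not report.ok:
            raise EventValidationError(report)
        out[str(pid)] = series
    return out


def read_event_table(
    path, dialect: str | Mapping[int, str] = "activpal_crea", strict: bool = True
) -> EventSeries:
    """Read a single-participant event table (see :func:`read_cohort_table`)."""
    cohort = read_cohort_table(path, dialect=dialect, strict=strict)
    if len(cohort) != 1:
        raise EventTableError(
            f"{path}: expected a single participant, found {len(cohort)}; use read_cohort_table"
        )
    return next(iter(cohort.values()))


def _serialise(series: EventSeries) -> pd.DataFrame:
    inv = _inverse_dialect(_dialect_map(series.dialect))
    frame = series.frame
    return pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "start": frame["start"].dt.strftime(_TIME_FORMAT),
            "duration_s": frame["duration_s"].map(lambda v: f"{v:.3f}"),
            "activity_code": frame["activity"].map(inv).astype(int),
            "steps": frame["steps"].astype(int),
        }
    )


def write_event_table(series: EventSeries, path) -> None:
    """Write a series to canonical CSV (ISO-8601 starts, millisecond durations).

    The representation is a fixed point: reading the file back and writing it
    again reproduces it byte for byte.
    """
    if series.empty:
        raise EventTableError("refusing to write an empty event series")
    _serialise(series).to_csv(path, index=False)


def write_cohort_table(cohort: Mapping[str, EventSeries] | list[EventSeries], path) -> None:
    """Write several participants' series into one canonical CSV."""
    series_list = list(cohort.values()) if isinstance(cohort, Mapping) else list(cohort)
    if not series_list:
        raise EventTableError("refusing to write an empty cohort")
    pd.concat([_serialise(s) for s in series_list], ignore_index=True).to_csv(path, index=False)


#: Maximum tolerated gap (seconds) between consecutive events before the
#: series is considered discontinuous.  Event tables are second-resolution, so
#: anything under a second is rounding.
_GAP_TOLERANCE_S = 1.0


def validate_series(series: EventSeries) -> ValidationReport:
    """Check the event-model invariants; report issues, never raise.

    Rules: ``empty``, ``negative_duration``, ``steps_on_non_stepping``,
    ``unsorted``, ``overlap``, and ``gap`` (a hole between consecutive events
    with no non-wear on either side).
    """
    report = ValidationReport()
    frame = series.frame
    if frame.empty:
        report.add(-1, "empty", "series has no events")
        return report

    for row in np.flatnonzero((frame["duration_s"] < 0).to_numpy()):
        report.add(int(row), "negative_duration", f"duration {frame['duration_s'].iloc[row]} < 0")

    bad_steps = (frame["steps"] > 0) & (frame["activity"] != "stepping")
    for row in np.flatnonzero(bad_steps.to_numpy()):
        report.add(
            int(row),
            "steps_on_non_stepping",
            f"{frame['steps'].iloc[row]} steps on a {frame['activity'].iloc[row]} event",
        )

    starts = frame["start"].to_numpy()
    ends = series.ends.to_numpy()
    order = np.diff(starts.astype("datetime64[ns]").astype("int64"))
    for row in np.flatnonzero(order < 0):
        report.add(int(row) + 1, "unsorted", "start precedes the previous event's start")

    gap_s = (starts[1:] - ends[:-1]).astype("timedelta64[ns]").astype("int64") / 1e9
    activity = frame["activity"].to_numpy()
    for row in np.flatnonzero(gap_s < -_GAP_TOLERANCE_S / 1000):
        report.add(int(row) + 1, "overlap", f"starts {-gap_s[row]:.3f}s before the previous event ends")
    nonwear_adjacent = (activity[1:] == "nonwear") | (activity[:-1] == "nonwear")
    for row in np.flatnonzero((gap_s > _GAP_TOLERANCE_S) & ~nonwear_adjacent):
        report.add(int(row) + 1, "gap", f"{gap_s[row]:.1f}s hole with no non-wear boundary")

    return report
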