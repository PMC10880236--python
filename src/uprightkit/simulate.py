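"""Synthetic posture-event cohorts with known ground truth.

Real thigh-accelerometer cohort data of the kind this pipeline targets are
access-restricted, so every stage is tested against simulated cohorts whose
generating parameters are known exactly.  The generator emulates the
statistical structure the analysis assumes:

* per participant, a multi-day event stream: a partial attachment day
  followed by full days, each filled from a drawn wake time (06:00–08:00) to
  a drawn sleep onset (22:30–23:30) by an alternating renewal process of
  upright events and sedentary gaps, with one long sedentary "sleep" event
  crossing each midnight;
* within each upright event, alternating standing and stepping sub-events
  (all at least 10 s, integer seconds) targeting a configured stepping
  proportion, with steps accumulated at a per-event cadence draw;
* sedentary gaps drawn from a gamma distribution whose shape parameter is
  the *dispersion knob*: large shape gives near-regular gaps (day-level
  upright burstiness near -1), small shape gives bursty days;
* person-level heterogeneity via lognormal multipliers on event duration and
  gap scale, and normal draws of cadence and stepping proportion;
* covariates drawn from configured marginals, with configured effects added
  to person-level parameters, recorded in a truth table.

Default rates and levels are anchored to published descriptive statistics
for mid-life UK adults wearing activPAL devices (about 53 upright events per
day, 6.4 h/d upright, roughly 36 % of upright time stepping, cadence near
90 steps/min, 16 h/d waking wear): they are calibration targets for
self-consistency checks, not claims about any real cohort.

Two generation paths are provided.  :func:`generate_cohort` produces full
event streams for end-to-end pipeline runs.  :func:`generate_person_summaries`
draws person-level metric summaries directly from the truth model (metric =
baseline + covariate effects + person noise + day-averaged noise), which is
what the regression-recovery simulations use: it isolates the model-fitting
stage and makes hundreds of replicates at cohort scale affordable.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .events import EventSeries

__all__ = [
    "CovariateEffect",
    "SimConfig",
    "TruthTable",
    "Cohort",
    "generate_cohort",
    "generate_day",
    "generate_person_summaries",
    "truth_metrics",
    "DEFAULT_COVARIATE_MARGINALS",
    "DEFAULT_EFFECTS",
    "METRIC_MODEL",
]

#: Covariate level frequencies, roughly matching a mid-life UK cohort.
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.478, "female": 0.522},
    "education": {"none": 0.234, "gcse": 0.310, "fe": 0.159, "he": 0.297},
    "disability": {"none": 0.876, "some_extent": 0.098, "severely_hampered": 0.026},
    "self_rated_health": {
        "excellent": 0.205,
        "very_good": 0.393,
        "good": 0.277,
        "fair": 0.104,
        "poor": 0.021,
    },
    "nssec": {"professional": 0.533, "intermediate": 0.323, "routine": 0.144},
    "bmi_category": {
        "normal": 0.310,
        "overweight": 0.383,
        "obese": 0.260,
        "morbidly_obese": 0.027,
        "underweight": 0.020,
    },
    "occupation_activity": {
        "sitting": 0.552,
        "standing": 0.158,
        "physical_work": 0.243,
        "heavy_manual": 0.047,
    },
    "smoking": {"never": 0.514, "past": 0.324, "occasional": 0.046, "daily": 0.116},
}

#: Person-summary metric truth model for the direct (summary-level) path:
#: name -> (baseline, between-person SD, within-person day SD).
METRIC_MODEL: dict[str, tuple[float, float, float]] = {
    "waking_wear_h": (16.2, 0.85, 0.5),
    "upright_events_n": (52.9, 14.5, 8.0),
    "stepping_events_n": (198.4, 66.0, 25.0),
    "upright_h": (6.4, 1.8, 0.8),
    "stepping_h": (2.0, 0.65, 0.3),
    "daily_steps": (9389.0, 3400.0, 1600.0),
    "step_weighted_cadence": (89.5, 8.5, 2.5),
    "stepping_event_duration_s": (31.0, 8.0, 3.0),
    "steps_per_stepping_event": (44.1, 16.0, 5.0),
    "burstiness_upright": (0.29, 0.088, 0.05),
    "burstiness_sedentary": (0.275, 0.082, 0.05),
    "upright_event_duration_min": (7.9, 3.7, 1.5),
    "stepping_proportion_pct": (35.6, 6.1, 2.5),
    "stepping_events_per_upright_event": (9.0, 3.8, 1.5),
    "steps_per_upright_event": (188.0, 88.0, 30.0),
}


class CovariateEffect(BaseModel):
    """A known additive effect of one covariate level on one person-level metric."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    factor: str
    level: str
    metric: str
    value: float


#: Default injected effects (on the person-summary scale).  In event-stream
#: mode only the upright-event-rate, cadence and stepping-proportion effects
#: can be realised mechanistically; the rest apply on the direct summary path.
DEFAULT_EFFECTS: tuple[CovariateEffect, ...] = (
    CovariateEffect(factor="sex", level="female", metric="upright_events_n", value=4.39),
    CovariateEffect(factor="sex", level="female", metric="burstiness_upright", value=0.05),
    CovariateEffect(factor="bmi_category", level="obese", metric="upright_events_n", value=-6.38),
    CovariateEffect(factor="bmi_category", level="obese", metric="daily_steps", value=-1232.63),
    CovariateEffect(
        factor="occupation_activity", level="physical_work", metric="upright_h", value=1.046
    ),
)

#: Metrics the event-stream generator can realise mechanistically, with the
#: person parameter they act on.
_EVENT_MODE_METRICS = {
    "upright_events_n": "events_per_day",
    "step_weighted_cadence": "cadence_mean",
    "stepping_proportion_pct": "stepping_proportion",
}


class SimConfig(BaseModel):
    """Generator parameters.  Identical config + seed gives identical output."""

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(default=100, gt=0)
    #: full recording days after the partial attachment day
    n_days: int = Field(default=7, gt=0)
    start_date: dt.date = dt.date(2017, 5, 1)

    #: daily wake time and sleep onset, hours, drawn uniformly per day
    wake_time_h: tuple[float, float] = (6.0, 8.0)
    sleep_time_h: tuple[float, float] = (22.5, 23.5)
    attach_time_h: tuple[float, float] = (12.0, 16.0)

    #: target mean daily upright-event count; the per-person sedentary gap
    #: mean is derived from it, the duration mean and the waking window
    upright_events_per_day: float = Field(default=52.9, gt=1)
    #: upright-event duration: lognormal, cohort mean (min) and CV
    upright_duration_mean_min: float = Field(default=7.26, gt=0)
    upright_duration_cv: float = Field(default=1.6, gt=0)
    #: gamma shape of the sedentary gap between upright events (the
    #: dispersion knob: small shape -> bursty days, large -> regular)
    sedentary_gap_shape: float = Field(default=0.3, gt=0)

    #: within-upright substructure
    stepping_proportion: float = Field(default=0.356, gt=0, lt=1)
    stepping_proportion_person_sd: float = Field(default=0.06, ge=0)
    stepping_event_duration_s: float = Field(default=31.0, ge=10)

    #: cadence (steps/min)
    cadence_mean: float = Field(default=89.5, gt=0)
    cadence_person_sd: float = Field(default=8.8, ge=0)
    cadence_event_sd: float = Field(default=5.0, ge=0)

    #: person-level lognormal multiplier CVs
    person_rate_cv: float = Field(default=0.25, ge=0)
    person_duration_cv: float = Field(default=0.20, ge=0)

    #: probability a participant removes the device mid-study (non-wear bout
    #: injected; everything after it is discarded by the cleaning stage)
    nonwear_probability: float = Field(default=0.0, ge=0, le=1)

    covariate_marginals: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    effects: tuple[CovariateEffect, ...] = DEFAULT_EFFECTS

    @model_validator(mode="after")
    def _feasible(self) -> "SimConfig":
        if self.wake_time_h[0] >= self.sleep_time_h[0]:
            raise ValueError("wake window must open before sleep window")
        window_min = (np.mean(self.sleep_time_h) - np.mean(self.wake_time_h)) * 60.0
        if self.upright_duration_mean_min >= window_min:
            raise ValueError(
                f"mean upright event duration {self.upright_duration_mean_min} min "
                f"exceeds the {window_min:.0f} min waking window"
            )
        if self.upright_events_per_day * self.upright_duration_mean_min >= window_min:
            raise ValueError(
                "infeasible config: upright_events_per_day x upright_duration_mean_min "
                f"({self.upright_events_per_day * self.upright_duration_mean_min:.0f} min) "
                f"exceeds the {window_min:.0f} min waking window"
            )
        for factor, marg in self.covariate_marginals.items():
            if not math.isclose(sum(marg.values()), 1.0, abs_tol=0.02):
                raise ValueError(f"marginals for {factor!r} do not sum to 1")
        return self

    @property
    def mean_window_min(self) -> float:
        return (float(np.mean(self.sleep_time_h)) - float(np.mean(self.wake_time_h))) * 60.0


@dataclass
class TruthTable:
    """Ground truth: per-person generating parameters and injected effects."""

    persons: pd.DataFrame
    effects: pd.DataFrame


@dataclass
class Cohort:
    """One generated cohort: event streams, covariates, and the truth table."""

    series: list[EventSeries]
    covariates: pd.DataFrame
    truth: TruthTable


# ---------------------------------------------------------------------------
# covariates and person parameters


def _draw_covariates(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    row = {}
    for factor, marg in config.covariate_marginals.items():
        levels = list(marg)
        probs = np.array([marg[l] for l in levels], dtype=float)
        row[factor] = str(rng.choice(levels, p=probs / probs.sum()))
    return row


def _effect_sum(config: SimConfig, covariates: dict[str, str], metric: str) -> float:
    return sum(
        e.value
        for e in config.effects
        if e.metric == metric and covariates.get(e.factor) == e.level
    )


def _person_params(
    config: SimConfig, covariates: dict[str, str], rng: np.random.Generator
) -> dict[str, float]:
    """Draw one participant's generating parameters, with event-mode effects applied."""

    def ln_mult(cv: float) -> float:
        if cv == 0:
            return 1.0
        s2 = math.log1p(cv * cv)
        return float(rng.lognormal(-s2 / 2.0, math.sqrt(s2)))

    dur_mean = config.upright_duration_mean_min * ln_mult(config.person_duration_cv)
    rate = config.upright_events_per_day * ln_mult(config.person_rate_cv)
    rate = max(rate + _effect_sum(config, covariates, "upright_events_n"), 4.0)

    # A day opens with an upright event and truncates at sleep onset, so the
    # realised count over a window W is ~ (W + gap) / (dur + gap); solve that
    # for the gap mean to make the configured rate the realised expectation.
    window = config.mean_window_min
    gap_mean = max((window - rate * dur_mean) / (rate - 1.0), 0.5)

    cadence = rng.normal(
        config.cadence_mean + _effect_sum(config, covariates, "step_weighted_cadence"),
        config.cadence_person_sd,
    )
    prop = rng.normal(
        config.stepping_proportion
        + _effect_sum(config, covariates, "stepping_proportion_pct") / 100.0,
        config.stepping_proportion_person_sd,
    )
    return {
        "upright_duration_mean_min": dur_mean,
        "sedentary_gap_mean_min": gap_mean,
        "sedentary_gap_shape": config.sedentary_gap_shape,
        "events_per_day": rate,
        "cadence_mean": float(np.clip(cadence, 40.0, 140.0)),
        "stepping_proportion": float(np.clip(prop, 0.08, 0.80)),
    }


# ---------------------------------------------------------------------------
# event-stream generation


def _split_total(total: int, parts: int, minimum: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` seconds into ``parts`` integer pieces, each >= minimum."""
    spare = total - minimum * parts
    weights = rng.dirichlet(np.ones(parts))
    extras = np.floor(weights * spare).astype(int)
    extras[0] += spare - int(extras.sum())
    return [minimum + int(e) for e in extras]


def _split_upright(
    dur_s: int, params: dict[str, float], config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Decompose one upright event into alternating standing/stepping sub-events.

    Returns ``(activity, duration_s, steps)`` tuples whose durations sum to
    ``dur_s``; every sub-event is at least 10 s.  Short events degrade to a
    single standing (or standing+stepping) event when the alternating pattern
    cannot fit.
    """
    prop = params["stepping_proportion"]
    step_total = int(round(prop * dur_s))
    stand_total = dur_s - step_total
    if dur_s < 20 or step_total < 10:
        # too short to alternate: a single sub-event, typed stepping with
        # probability `prop` so the expected stepping proportion is unbiased
        pieces = [("stepping" if rng.random() < prop else "standing", dur_s, 0)]
        return _assign_steps(pieces, params, config, rng)

    k = max(1, int(round(step_total / config.stepping_event_duration_s)))
    k = min(k, step_total // 10, max(stand_total // 10 - 1, 0))
    if k < 1:
        if stand_total >= 10:
            pieces = [("standing", stand_total, 0), ("stepping", step_total, 0)]
        else:
            pieces = [("stepping", dur_s, 0)]
    else:
        step_durs = _split_total(step_total, k, 10, rng)
        stand_durs = _split_total(stand_total, k + 1, 10, rng)
        pieces = []
        for i in range(k):
            pieces.append(("standing", stand_durs[i], 0))
            pieces.append(("stepping", step_durs[i], 0))
        pieces.append(("standing", stand_durs[k], 0))
    return _assign_steps(pieces, params, config, rng)


def _assign_steps(
    pieces: list[tuple[str, int, int]],
    params: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    out = []
    for activity, d, _ in pieces:
        steps = 0
        if activity == "stepping":
            cadence = max(20.0, rng.normal(params["cadence_mean"], config.cadence_event_sd))
            steps = max(1, int(round(cadence * d / 60.0)))
        out.append((activity, d, steps))
    return out


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    s2 = math.log1p(cv * cv)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _fill_waking(
    params: dict[str, float],
    t0: dt.datetime,
    t1: dt.datetime,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[dt.datetime, int, str, int]]:
    """Alternate upright events and sedentary gaps over ``[t0, t1)``.

    The window opens with an upright event (the arise); a remainder gap that
    would cross ``t1`` is left to be absorbed by the caller's sleep event, so
    the stream stays contiguous.
    """
    mu, sigma = _lognormal_params(params["upright_duration_mean_min"] * 60.0, config.upright_duration_cv)
    shape = params["sedentary_gap_shape"]
    gap_scale = params["sedentary_gap_mean_min"] * 60.0 / shape

    rows: list[tuple[dt.datetime, int, str, int]] = []
    t = t0
    while t < t1:
        dur = max(10, int(round(rng.lognormal(mu, sigma))))
        remaining = int((t1 - t).total_seconds())
        if dur > remaining:
            dur = remaining
            if dur < 10:
                break
        for activity, d, steps in _split_upright(dur, params, config, rng):
            rows.append((t, d, activity, steps))
            t += dt.timedelta(seconds=d)
        gap = max(10, int(round(rng.gamma(shape, gap_scale))))
        if t + dt.timedelta(seconds=gap) >= t1:
            break
        rows.append((t, gap, "sedentary", 0))
        t += dt.timedelta(seconds=gap)
    return rows


def generate_day(
    params: dict[str, float],
    date: dt.date,
    rng: np.random.Generator,
    config: SimConfig | None = None,
) -> list[tuple[dt.datetime, int, str, int]]:
    """Generate one full day's waking events (wake to sleep onset, no sleep filler)."""
    config = config or SimConfig()
    wake = dt.datetime.combine(date, dt.time.min) + dt.timedelta(hours=float(rng.uniform(*config.wake_time_h)))
    sleep = dt.datetime.combine(date, dt.time.min) + dt.timedelta(hours=float(rng.uniform(*config.sleep_time_h)))
    wake = wake.replace(microsecond=0)
    sleep = sleep.replace(microsecond=0)
    return _fill_waking(params, wake, sleep, config, rng)


def _generate_stream(
    params: dict[str, float], config: SimConfig, rng: np.random.Generator
) -> list[tuple[dt.datetime, int, str, int]]:
    """Attachment day plus ``n_days`` full days, contiguous across midnights."""
    day0 = config.start_date
    wake_h = [float(rng.uniform(*config.wake_time_h)) for _ in range(config.n_days + 1)]
    sleep_h = [float(rng.uniform(*config.sleep_time_h)) for _ in range(config.n_days + 1)]

    def at(day_index: int, hours: float) -> dt.datetime:
        base = dt.datetime.combine(day0 + dt.timedelta(days=day_index), dt.time.min)
        return (base + dt.timedelta(hours=hours)).replace(microsecond=0)

    rows: list[tuple[dt.datetime, int, str, int]] = []
    attach = at(0, float(rng.uniform(*config.attach_time_h)))
    rows.extend(_fill_waking(params, attach, at(0, sleep_h[0]), config, rng))
    for d in range(1, config.n_days + 1):
        sleep_start = rows[-1][0] + dt.timedelta(seconds=rows[-1][1])
        wake = at(d, wake_h[d])
        rows.append((sleep_start, int((wake - sleep_start).total_seconds()), "sedentary", 0))
        rows.extend(_fill_waking(params, wake, at(d, sleep_h[d]), config, rng))
    return rows


def _inject_nonwear(
    rows: list[tuple[dt.datetime, int, str, int]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[dt.datetime, int, str, int]]:
    """Replace the stream tail from a random mid-study point with a non-wear bout."""
    day = int(rng.integers(1, config.n_days + 1))
    hour = float(rng.uniform(9.0, 20.0))
    cut_at = dt.datetime.combine(config.start_date + dt.timedelta(days=day), dt.time.min) + dt.timedelta(hours=hour)
    kept = [r for r in rows if r[0] + dt.timedelta(seconds=r[1]) <= cut_at]
    if not kept:
        kept = rows[:1]
    t = kept[-1][0] + dt.timedelta(seconds=kept[-1][1])
    kept.append((t, 6 * 3600, "nonwear", 0))
    return kept


def generate_cohort(config: SimConfig, seed: int) -> Cohort:
    """Generate per-participant event streams, covariates, and the truth table."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(config.n_participants)

    series: list[EventSeries] = []
    cov_rows = []
    person_rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:04d}"
        covariates = _draw_covariates(config, rng)
        params = _person_params(config, covariates, rng)
        rows = _generate_stream(params, config, rng)
        if config.nonwear_probability > 0 and rng.random() < config.nonwear_probability:
            rows = _inject_nonwear(rows, config, rng)
        frame = pd.DataFrame(
            {
                "start": [r[0] for r in rows],
                "duration_s": [float(r[1]) for r in rows],
                "activity": [r[2] for r in rows],
                "steps": [r[3] for r in rows],
            }
        )
        frame["start"] = pd.to_datetime(frame["start"])
        series.append(EventSeries(pid, frame))
        cov_rows.append({"participant_id": pid, **covariates})
        person_rows.append({"participant_id": pid, **params})

    effects = pd.DataFrame(
        {
            "factor": [e.factor for e in config.effects],
            "level": [e.level for e in config.effects],
            "metric": [e.metric for e in config.effects],
            "value": [e.value for e in config.effects],
            "event_mode": [e.metric in _EVENT_MODE_METRICS for e in config.effects],
        }
    )
    truth = TruthTable(persons=pd.DataFrame(person_rows), effects=effects)
    return Cohort(series=series, covariates=pd.DataFrame(cov_rows), truth=truth)


# ---------------------------------------------------------------------------
# direct summary-level generation and truth expectations


def generate_person_summaries(config: SimConfig, seed: int) -> tuple[pd.DataFrame, TruthTable]:
    """Draw person-level summaries straight from the truth model.

    Every metric in :data:`METRIC_MODEL` is generated as baseline + injected
    covariate effects + a between-person draw + the mean of ``n_days``
    within-person day draws; ``standing_h`` is derived as ``upright_h -
    stepping_h`` so the composition identity holds.  Metric noise terms are
    mutually independent, so the injected coefficients are the true mutually
    adjusted regression coefficients.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = config.n_participants
    rows = []
    for i in range(n):
        covariates = _draw_covariates(config, rng)
        rows.append({"participant_id": f"P{i + 1:04d}", **covariates})
    frame = pd.DataFrame(rows)

    for metric, (baseline, person_sd, day_sd) in METRIC_MODEL.items():
        effect = np.zeros(n)
        for e in config.effects:
            if e.metric == metric:
                effect += np.where(frame[e.factor] == e.level, e.value, 0.0)
        values = (
            baseline
            + effect
            + rng.normal(0.0, person_sd, n)
            + rng.normal(0.0, day_sd / math.sqrt(config.n_days), n)
        )
        frame[metric] = values
    frame["standing_h"] = frame["upright_h"] - frame["stepping_h"]
    frame["n_valid_days"] = config.n_days

    effects = pd.DataFrame(
        {
            "factor": [e.factor for e in config.effects],
            "level": [e.level for e in config.effects],
            "metric": [e.metric for e in config.effects],
            "value": [e.value for e in config.effects],
            "event_mode": [e.metric in _EVENT_MODE_METRICS for e in config.effects],
        }
    )
    return frame, TruthTable(persons=frame[["participant_id"]].copy(), effects=effects)


def truth_metrics(config: SimConfig, truth: TruthTable) -> pd.DataFrame:
    """Large-sample expectations of the headline metrics per participant.

    Renewal expectations for the event-stream generator: the daily upright
    event count is the configured rate, upright hours are rate x mean event
    duration, stepping hours are upright hours x stepping proportion, and the
    step-weighted cadence is the person's cadence mean (symmetric event
    noise, weights nearly independent of the noise).
    """
    p = truth.persons
    out = pd.DataFrame({"participant_id": p["participant_id"]})
    out["upright_events_n"] = p["events_per_day"]
    out["upright_h"] = p["events_per_day"] * p["upright_duration_mean_min"] / 60.0
    out["stepping_h"] = out["upright_h"] * p["stepping_proportion"]
    out["stepping_proportion_pct"] = 100.0 * p["stepping_proportion"]
    out["step_weighted_cadence"] = p["cadence_mean"]
    return out
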