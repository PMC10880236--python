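"""One-command orchestration: simulate/ingest -> segment -> compose -> metrics -> model.

The pipeline mirrors the cleaning and derivation order of an event-based
posture analysis: truncate each participant's stream at the first non-wear
bout, cut waking days, apply the valid-day and six-valid-day inclusion
gates, build upright events, derive daily and person-level metrics, and fit
the mutually adjusted association models.  A JSON manifest records the
configuration hash and the attrition count at every gate so a run is
auditable and reruns with the same configuration and seed are
byte-reproducible.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .composition import build_posture_events, person_mean_composition
from .events import EventSeries, read_cohort_table, validate_series, write_cohort_table
from .metrics import daily_summary, person_summary
from .models import (
    DEFAULT_FACTOR_REFERENCES,
    default_model_specs,
    fit_metric_model,
    results_table,
    sensitivity_exclude,
)
from .segmentation import (
    filter_valid_days,
    include_participant,
    segment_waking_days,
    truncate_at_first_nonwear,
)
from .simulate import SimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_MODEL_OUTCOMES = (
    "upright_events_n",
    "upright_h",
    "standing_h",
    "stepping_h",
    "burstiness_upright",
    "burstiness_sedentary",
    "daily_steps",
    "step_weighted_cadence",
    "upright_event_duration_min",
    "stepping_proportion_pct",
)


class PipelineConfig(BaseModel):
    """Full pipeline configuration; round-trips through YAML, unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "pipeline_out"

    # input: either a simulation config or paths to event/covariate CSVs
    simulate: Optional[SimConfig] = Field(default_factory=SimConfig)
    events_path: Optional[str] = None
    covariates_path: Optional[str] = None
    dialect: str = "activpal_crea"

    # cleaning / segmentation
    anchor_time: dt.time = dt.time(3, 0)
    min_wear_h: float = 10.0
    min_upright_events: int = 4
    min_valid_days: int = 6
    event_floor_s: float = 10.0

    # metric conventions
    cadence_min_steps: int = 10
    composition_mean: Literal["pooled", "daily"] = "pooled"
    sd_convention: Literal["population", "sample"] = "population"
    n_convention: Literal["events", "intervals"] = "events"

    # modelling
    run_models: bool = True
    glm_family: str = "gaussian"
    model_outcomes: tuple[str, ...] = DEFAULT_MODEL_OUTCOMES
    sensitivity_exclusions: tuple[tuple[str, ...], ...] = (
        ("severely_hampered",),
        ("severely_hampered", "some_extent"),
    )

    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def summarise_participant(series: EventSeries, config: PipelineConfig) -> dict:
    """Run cleaning, segmentation, composition and metrics for one participant.

    Returns a dict with the participant's gate outcomes, and — when included —
    the person-summary metric row plus per-day and per-upright-event tables.
    """
    out: dict = {"participant_id": series.participant_id, "included": False}
    truncated = truncate_at_first_nonwear(series)
    out["truncated_at_nonwear"] = len(truncated) < len(series)
    days = segment_waking_days(
        truncated, anchor=config.anchor_time, min_upright_s=config.event_floor_s
    )
    validities = filter_valid_days(
        days,
        min_wear_h=config.min_wear_h,
        min_upright_events=config.min_upright_events,
        floor_s=config.event_floor_s,
    )
    out["n_days_segmented"] = len(days)
    out["n_days_valid"] = sum(v.valid for v in validities)
    if not include_participant(validities, min_valid_days=config.min_valid_days):
        return out

    daily_rows = []
    upright_rows = []
    events_by_day = []
    for v in validities:
        if not v.valid:
            continue
        posture = build_posture_events(v.day, floor_s=config.event_floor_s)
        daily_rows.append(
            daily_summary(
                v.day,
                posture,
                cadence_min_steps=config.cadence_min_steps,
                sd_convention=config.sd_convention,
                n_convention=config.n_convention,
            )
        )
        events_by_day.append(posture.upright)
        for e in posture.upright:
            upright_rows.append(
                {
                    "participant_id": series.participant_id,
                    "date": v.day.date.isoformat(),
                    "start": e.start.isoformat(),
                    "duration_min": e.duration_min,
                    "standing_min": e.standing_min,
                    "stepping_min": e.stepping_min,
                    "n_stepping_events": e.n_stepping_events,
                    "step_count": e.step_count,
                }
            )
    composition = person_mean_composition(events_by_day, method=config.composition_mean)
    out["included"] = True
    out["summary"] = person_summary(series.participant_id, daily_rows, composition=composition)
    out["daily"] = daily_rows
    out["upright_rows"] = upright_rows
    return out


def _fit_models(summary: pd.DataFrame, config: PipelineConfig, out_dir: Path, manifest: dict) -> None:
    # keep only factors that are actually identifiable in this sample
    factors = {}
    for name, ref in DEFAULT_FACTOR_REFERENCES.items():
        if name not in summary.columns:
            continue
        levels = summary[name].dropna().unique()
        if len(levels) >= 2 and ref in levels:
            factors[name] = ref
        else:
            log.warning("factor %s skipped: fewer than two levels (or no reference) in sample", name)
    outcomes = [o for o in config.model_outcomes if o in summary.columns]
    if not factors or not outcomes:
        manifest["models"] = {"fitted": 0, "skipped": "no identifiable factors or outcomes"}
        return
    specs = default_model_specs(outcomes, factors=factors, family=config.glm_family)
    results = {}
    skipped = {}
    for spec in specs:
        try:
            results[spec.outcome] = fit_metric_model(summary, spec)
        except ValueError as err:  # aliased design or unidentifiable factor at small n
            log.warning("model for %s skipped: %s", spec.outcome, err)
            skipped[spec.outcome] = str(err)
    if not results:
        manifest["models"] = {"fitted": 0, "skipped_outcomes": skipped}
        return
    table = results_table(results)
    table.to_csv(out_dir / "model_coefficients.csv", index=False)
    vif = pd.DataFrame({o: r.vif for o, r in results.items()})
    vif.to_csv(out_dir / "model_vif.csv")
    manifest["models"] = {
        "fitted": len(results),
        "outcomes": list(results),
        "max_vif": float(vif.max().max()),
    }
    if skipped:
        manifest["models"]["skipped_outcomes"] = skipped

    if "disability" in factors:
        for drop in config.sensitivity_exclusions:
            label = "excl_" + "_".join(drop)
            try:
                sens = sensitivity_exclude(summary, specs, list(drop), factor="disability")
            except ValueError as err:
                log.warning("sensitivity %s skipped: %s", label, err)
                continue
            results_table(sens).to_csv(out_dir / f"model_coefficients_{label}.csv", index=False)
            manifest.setdefault("sensitivity", {})[label] = {
                "n": int(next(iter(sens.values())).nobs)
            }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "uprightkit_version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "config": config.model_dump(mode="json"),
    }

    if config.events_path:
        cohort_series = read_cohort_table(config.events_path, dialect=config.dialect, strict=False)
        series_list = list(cohort_series.values())
        covariates = (
            pd.read_csv(config.covariates_path) if config.covariates_path else pd.DataFrame()
        )
    elif config.simulate is not None:
        cohort = generate_cohort(config.simulate, config.seed)
        series_list = cohort.series
        covariates = cohort.covariates
        write_cohort_table(series_list, out_dir / "events.csv")
        covariates.to_csv(out_dir / "covariates.csv", index=False)
        cohort.truth.persons.to_csv(out_dir / "truth_persons.csv", index=False)
        cohort.truth.effects.to_csv(out_dir / "truth_effects.csv", index=False)
    else:
        raise ValueError("config must provide either events_path or a simulate block")

    validation_issues = sum(len(validate_series(s).issues) for s in series_list)
    manifest["validation_issues"] = validation_issues

    cov_by_pid = (
        covariates.set_index("participant_id").to_dict("index") if len(covariates) else {}
    )
    summaries, daily_rows, upright_rows = [], [], []
    n_included = 0
    n_days_segmented = n_days_valid = 0
    for series in series_list:
        result = summarise_participant(series, config)
        n_days_segmented += result["n_days_segmented"]
        n_days_valid += result["n_days_valid"]
        if not result["included"]:
            continue
        n_included += 1
        row = result["summary"]
        row.update(cov_by_pid.get(series.participant_id, {}))
        summaries.append(row)
        upright_rows.extend(result["upright_rows"])
        for d in result["daily"]:
            daily_rows.append({"participant_id": series.participant_id, **d.__dict__})

    manifest["attrition"] = {
        "participants_in": len(series_list),
        "excluded_min_valid_days": len(series_list) - n_included,
        "included": n_included,
        "days_segmented": n_days_segmented,
        "days_valid": n_days_valid,
        "upright_events": len(upright_rows),
    }

    summary = pd.DataFrame(summaries)
    summary.to_csv(out_dir / "person_summary.csv", index=False)
    pd.DataFrame(daily_rows).to_csv(out_dir / "daily_metrics.csv", index=False)
    pd.DataFrame(upright_rows).to_csv(out_dir / "upright_events.csv", index=False)
    manifest["person_summary_sha256"] = hashlib.sha256(
        (out_dir / "person_summary.csv").read_bytes()
    ).hexdigest()

    if config.run_models and n_included > 0:
        _fit_models(summary, config, out_dir, manifest)
    elif config.run_models:
        manifest["models"] = {"fitted": 0, "skipped": "no included participants"}

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
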