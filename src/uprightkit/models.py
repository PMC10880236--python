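"""Mutually adjusted association models between derived metrics and covariates.

Each person-level metric is regressed on the full set of categorical
sociodemographic and health factors simultaneously (treatment coding against
declared reference levels), additionally adjusted for mean waking wear time
and mean daily step count — except when the outcome *is* daily steps, where
the step-count adjustment is dropped.  The default family is Gaussian with an
identity link, so coefficients stay on the outcome's natural scale (minutes,
counts, steps/min, burstiness units) with conventional Wald 95 % confidence
intervals and ``* / ** / ***`` significance stars at 0.05 / 0.01 / 0.001.
No multiple-testing correction is applied.

Multicollinearity is screened with the variance inflation factor; factors
with more than one degree of freedom get the generalized VIF, reported on a
per-term scale (``GVIF^(1/df)``) so it is comparable with a 1-df VIF.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DEFAULT_FACTOR_REFERENCES",
    "ModelSpec",
    "ModelResult",
    "RankDeficientDesignError",
    "fit_metric_model",
    "compute_vif",
    "sensitivity_exclude",
    "default_model_specs",
    "results_table",
]

log = logging.getLogger(__name__)

#: Reference level of each categorical factor in the mutually adjusted models.
DEFAULT_FACTOR_REFERENCES: dict[str, str] = {
    "sex": "male",
    "education": "none",
    "disability": "none",
    "self_rated_health": "excellent",
    "nssec": "professional",
    "bmi_category": "normal",
    "occupation_activity": "sitting",
    "smoking": "never",
}

DEFAULT_ADJUSTMENTS = ("waking_wear_h", "daily_steps")

_FAMILIES = {
    "gaussian": lambda: sm.families.Gaussian(),
    "gamma_log": lambda: sm.families.Gamma(link=sm.families.links.Log()),
}


class RankDeficientDesignError(ValueError):
    """The design matrix is rank deficient; names the aliased column."""


@dataclass(frozen=True)
class ModelSpec:
    """One outcome's regression specification.

    ``factors`` maps each categorical covariate to its reference level;
    ``adjustments`` are continuous columns entered linearly.  The step-count
    adjustment is dropped automatically when the outcome is the daily step
    count itself.
    """

    outcome: str
    factors: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FACTOR_REFERENCES))
    adjustments: tuple[str, ...] = DEFAULT_ADJUSTMENTS
    family: str = "gaussian"

    def effective_adjustments(self) -> tuple[str, ...]:
        return tuple(a for a in self.adjustments if a != self.outcome)

    def formula(self) -> str:
        terms = [
            f"C({name}, Treatment(reference={ref!r}))" for name, ref in self.factors.items()
        ] + list(self.effective_adjustments())
        return f"{self.outcome} ~ " + " + ".join(terms)

    def columns(self) -> list[str]:
        return [self.outcome, *self.factors, *self.effective_adjustments()]


@dataclass
class ModelResult:
    """Fitted model summary: per-level coefficients, VIFs, bookkeeping."""

    spec: ModelSpec
    table: pd.DataFrame  # factor, level, n, B, ci_low, ci_high, p, stars
    vif: pd.Series  # per term (factor or adjustment)
    nobs: int
    fit: object  # statsmodels results, for diagnostics
    dropped_factors: tuple[str, ...] = ()


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


_TERM_RE = re.compile(r"^C\((?P<name>\w+), .*\)(\[T\.(?P<level>.+)\])?$")


def _parse_exog_name(name: str) -> tuple[str, str | None]:
    """Map a patsy column name to (term, level); plain columns map to themselves."""
    m = _TERM_RE.match(name)
    if m:
        return m.group("name"), m.group("level")
    return name, None


def _check_full_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank == exog.shape[1]:
        return
    # walk the columns and name the first one linearly dependent on its predecessors
    for j in range(1, exog.shape[1]):
        if np.linalg.matrix_rank(exog[:, : j + 1]) <= np.linalg.matrix_rank(exog[:, :j]):
            raise RankDeficientDesignError(
                f"design matrix is rank deficient: column {names[j]!r} is aliased"
            )
    raise RankDeficientDesignError("design matrix is rank deficient")


def fit_metric_model(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one mutually adjusted GLM on complete-case rows.

    Raises :class:`RankDeficientDesignError` on an aliased design and
    ``ValueError`` when a factor has fewer than two observed levels.
    """
    cols = spec.columns()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"outcome {spec.outcome!r}: missing columns {missing}")
    frame = data[cols].dropna().copy()
    if frame.empty:
        raise ValueError(f"outcome {spec.outcome!r}: no complete-case rows")
    for name, ref in spec.factors.items():
        levels = frame[name].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} has a single observed level {levels!r}")
        if ref not in levels:
            raise ValueError(f"factor {name!r}: reference level {ref!r} not present")

    model = smf.glm(spec.formula(), data=frame, family=_FAMILIES[spec.family]())
    _check_full_rank(np.asarray(model.exog), list(model.exog_names))
    fit = model.fit()

    ci = fit.conf_int(alpha=0.05)
    rows = []
    for name in fit.params.index:
        term, level = _parse_exog_name(name)
        if name == "Intercept":
            continue
        n = int((frame[term] == level).sum()) if level is not None else len(frame)
        rows.append(
            {
                "factor": term,
                "level": level if level is not None else "(linear)",
                "n": n,
                "B": float(fit.params[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
                "p": float(fit.pvalues[name]),
                "stars": _stars(float(fit.pvalues[name])),
            }
        )
    table = pd.DataFrame(rows)

    exog = pd.DataFrame(np.asarray(model.exog), columns=list(model.exog_names))
    term_columns: dict[str, list[str]] = {}
    for name in exog.columns:
        if name == "Intercept":
            continue
        term, _ = _parse_exog_name(name)
        term_columns.setdefault(term, []).append(name)
    vif = compute_vif(exog.drop(columns=["Intercept"]), term_columns)

    return ModelResult(spec=spec, table=table, vif=vif, nobs=len(frame), fit=fit)


def compute_vif(exog: pd.DataFrame, terms: Mapping[str, list[str]] | None = None) -> pd.Series:
    """Per-term (generalized) variance inflation factors.

    ``exog`` holds the non-intercept design columns.  For a term with ``df``
    columns the generalized VIF is ``det(R_t) det(R_o) / det(R)`` where ``R``
    is the correlation matrix of all columns and ``R_t`` / ``R_o`` its
    restrictions to the term's columns and the others; it is reported on the
    per-term scale ``GVIF^(1/df)``, which reduces to the ordinary VIF for a
    single-column term.  Perfect collinearity reports ``inf``.
    """
    if terms is None:
        terms = {c: [c] for c in exog.columns}
    X = exog.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    R = np.corrcoef((X / sd).T) if X.shape[1] > 1 else np.ones((1, 1))
    R = np.atleast_2d(R)
    det_R = float(np.linalg.det(R))
    idx = {c: i for i, c in enumerate(exog.columns)}

    out = {}
    for term, cols in terms.items():
        t = [idx[c] for c in cols]
        o = [i for i in range(len(exog.columns)) if i not in t]
        if det_R <= 1e-12:
            out[term] = np.inf
            continue
        det_t = float(np.linalg.det(R[np.ix_(t, t)])) if t else 1.0
        det_o = float(np.linalg.det(R[np.ix_(o, o)])) if o else 1.0
        gvif = det_t * det_o / det_R
        out[term] = float(gvif) ** (1.0 / len(t))
    return pd.Series(out, name="vif")


def default_model_specs(
    outcomes: Sequence[str],
    factors: Mapping[str, str] | None = None,
    adjustments: tuple[str, ...] = DEFAULT_ADJUSTMENTS,
    family: str = "gaussian",
) -> list[ModelSpec]:
    """One :class:`ModelSpec` per outcome with the shared factor set."""
    factors = dict(factors or DEFAULT_FACTOR_REFERENCES)
    return [ModelSpec(outcome=o, factors=factors, adjustments=adjustments, family=family) for o in outcomes]


def sensitivity_exclude(
    data: pd.DataFrame,
    specs: Sequence[ModelSpec],
    levels_to_drop: Sequence[str],
    factor: str = "disability",
) -> dict[str, ModelResult]:
    """Refit every spec after dropping participants at the given factor levels.

    When the exclusion collapses the factor to a single level, the factor is
    removed from the design with a warning rather than aborting the refit.
    """
    sub = data[~data[factor].isin(set(levels_to_drop))]
    if sub.empty:
        raise ValueError(f"excluding {list(levels_to_drop)} leaves an empty sample")
    out: dict[str, ModelResult] = {}
    for spec in specs:
        factors = dict(spec.factors)
        dropped: tuple[str, ...] = ()
        if factor in factors and sub[factor].nunique() < 2:
            warnings.warn(
                f"factor {factor!r} collapses to one level after exclusion; dropped from the design",
                stacklevel=2,
            )
            factors.pop(factor)
            dropped = (factor,)
        result = fit_metric_model(sub, replace(spec, factors=factors))
        result.dropped_factors = dropped
        out[spec.outcome] = result
    return out


def results_table(results: Mapping[str, ModelResult]) -> pd.DataFrame:
    """Side-by-side long table of coefficients across outcomes."""
    frames = []
    for outcome, res in results.items():
        t = res.table.copy()
        t.insert(0, "outcome", outcome)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
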