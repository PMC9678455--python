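"""Evaluation indices for the Monte-Carlo study.

Four indices summarise each design cell, separately per prior family and
per target parameter (the treatment effect ``b1`` and the nesting-effect
variance ``sigma2_U``):

* convergence rate — ``100 * r / R`` where ``r`` of the ``R`` replicates
  passed the convergence diagnostic;
* coverage — percentage of converged replicates whose 95% credible
  interval strictly contains the true value;
* bias — mean of (estimate - truth) over converged replicates;
* RMSE — root mean square of (estimate - truth) over converged replicates.

Bias and RMSE are stored on the raw parameter scale; a display multiplier
can be applied at table-formatting time only.  Grand summaries
(mean/median/min/max) and marginal summaries (means by one design factor)
are taken over the condition-level values, not over pooled replicates, so
a printed minimum or maximum is attributable to a single cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import SimulationCondition, TruthParameters

__all__ = [
    "PARAMETERS",
    "METRICS",
    "ReplicationRecord",
    "convergence_rate",
    "ci_coverage",
    "bias",
    "rmse",
    "true_value",
    "metric_table",
    "grand_summary",
    "marginal_summary",
]

#: Target parameters: the treatment effect b1 and the nesting variance.
PARAMETERS = ("treatment_effect", "nesting_effect")
METRICS = ("convergence_rate", "coverage", "bias", "rmse")

_CONDITION_COLS = ["c", "m", "rho", "prior"]


@dataclass(frozen=True)
class ReplicationRecord:
    """Posterior summaries of one fitted replicate.

    Estimate and interval fields may be ``None`` when the fit did not
    converge; converged records must carry all of them.
    """

    condition: SimulationCondition
    rep_id: int
    converged: bool
    truth: TruthParameters
    treatment_effect: float | None = None
    treatment_effect_low: float | None = None
    treatment_effect_high: float | None = None
    nesting_effect: float | None = None
    nesting_effect_low: float | None = None
    nesting_effect_high: float | None = None

    def __post_init__(self) -> None:
        if self.converged:
            fields = (
                self.treatment_effect,
                self.treatment_effect_low,
                self.treatment_effect_high,
                self.nesting_effect,
                self.nesting_effect_low,
                self.nesting_effect_high,
            )
            if any(v is None for v in fields):
                raise ValueError("converged records must carry all estimates")
            if (
                self.treatment_effect_low > self.treatment_effect_high
                or self.nesting_effect_low > self.nesting_effect_high
            ):
                raise ValueError("interval bounds out of order")

    def estimate(self, parameter: str) -> float | None:
        _check_parameter(parameter)
        return getattr(self, parameter)

    def interval(self, parameter: str) -> tuple[float | None, float | None]:
        _check_parameter(parameter)
        return (
            getattr(self, f"{parameter}_low"),
            getattr(self, f"{parameter}_high"),
        )


def _check_parameter(parameter: str) -> None:
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; expected {PARAMETERS}")


def true_value(truth: TruthParameters, parameter: str) -> float:
    """Truth value of a target parameter: b1 for the treatment effect,
    rho * total treatment variance for the nesting effect."""
    _check_parameter(parameter)
    return truth.b1 if parameter == "treatment_effect" else truth.sigma2_U


def convergence_rate(records: Sequence[ReplicationRecord]) -> float:
    """Percentage of replicates whose fit passed the convergence check."""
    if not records:
        raise ValueError("convergence rate of an empty record set is undefined")
    return 100.0 * sum(r.converged for r in records) / len(records)


def _converged(records: Iterable[ReplicationRecord]) -> list[ReplicationRecord]:
    return [r for r in records if r.converged]


def ci_coverage(records: Sequence[ReplicationRecord], parameter: str) -> float:
    """Percentage of converged replicates whose interval strictly contains
    the truth; NaN when no replicate converged."""
    _check_parameter(parameter)
    conv = _converged(records)
    if not conv:
        return math.nan
    hits = 0
    for r in conv:
        lo, hi = r.interval(parameter)
        truth = true_value(r.truth, parameter)
        hits += lo < truth < hi
    return 100.0 * hits / len(conv)


def bias(records: Sequence[ReplicationRecord], parameter: str) -> float:
    """Mean of (estimate - truth) over converged replicates; NaN if none."""
    _check_parameter(parameter)
    conv = _converged(records)
    if not conv:
        return math.nan
    errs = [r.estimate(parameter) - true_value(r.truth, parameter) for r in conv]
    return float(np.mean(errs))


def rmse(records: Sequence[ReplicationRecord], parameter: str) -> float:
    """Root mean square of (estimate - truth) over converged replicates;
    NaN if none."""
    _check_parameter(parameter)
    conv = _converged(records)
    if not conv:
        return math.nan
    errs = [r.estimate(parameter) - true_value(r.truth, parameter) for r in conv]
    return float(np.sqrt(np.mean(np.square(errs))))


def metric_table(records: Sequence[ReplicationRecord]) -> pd.DataFrame:
    """Aggregate replicate records into a tidy metric table.

    One row per (c, m, rho, prior, parameter, metric) with the metric
    value, the replicate count and the converged count.
    """
    if not records:
        raise ValueError("no records to aggregate")
    groups: dict[tuple, list[ReplicationRecord]] = {}
    for r in records:
        key = (r.condition.c, r.condition.m, r.condition.rho, r.condition.prior_family)
        groups.setdefault(key, []).append(r)

    rows = []
    for (c, m, rho, prior), recs in sorted(groups.items()):
        n_conv = len(_converged(recs))
        for parameter in PARAMETERS:
            values = {
                "convergence_rate": convergence_rate(recs),
                "coverage": ci_coverage(recs, parameter),
                "bias": bias(recs, parameter),
                "rmse": rmse(recs, parameter),
            }
            for metric, value in values.items():
                rows.append(
                    {
                        "c": c,
                        "m": m,
                        "rho": rho,
                        "prior": prior,
                        "parameter": parameter,
                        "metric": metric,
                        "value": value,
                        "n_reps": len(recs),
                        "n_converged": n_conv,
                    }
                )
    return pd.DataFrame(rows)


def _check_table(table: pd.DataFrame) -> None:
    required = set(_CONDITION_COLS + ["parameter", "metric", "value"])
    if not required <= set(table.columns):
        raise ValueError(f"metric table must contain columns {sorted(required)}")


def grand_summary(table: pd.DataFrame, report_scale: float = 1.0) -> pd.DataFrame:
    """Mean/median/min/max of every metric over the design cells, per
    prior family and parameter.

    ``report_scale`` multiplies bias and RMSE values for display only.
    """
    _check_table(table)
    table = _apply_scale(table, report_scale)
    grouped = table.groupby(["prior", "parameter", "metric"])["value"]
    out = grouped.agg(["mean", "median", "min", "max"]).reset_index()
    return out


def marginal_summary(
    table: pd.DataFrame, by: str, report_scale: float = 1.0
) -> pd.DataFrame:
    """Metric means over all cells sharing each level of one design factor
    (``c``, ``m`` or ``rho``), per prior family and parameter."""
    _check_table(table)
    if by not in ("c", "m", "rho"):
        raise ValueError("marginal factor must be one of 'c', 'm', 'rho'")
    table = _apply_scale(table, report_scale)
    grouped = table.groupby([by, "prior", "parameter", "metric"])["value"]
    return grouped.mean().reset_index()


def _apply_scale(table: pd.DataFrame, report_scale: float) -> pd.DataFrame:
    if report_scale == 1.0:
        return table
    table = table.copy()
    mask = table["metric"].isin(["bias", "rmse"])
    table.loc[mask, "value"] *= report_scale
    return table
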