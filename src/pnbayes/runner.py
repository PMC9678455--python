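"""Orchestration of the Monte-Carlo prior-comparison study.

A study is a grid of design cells (c treatment clusters, m subjects per
cluster, treatment-arm ICC rho), each replicated ``n_reps`` times.  Every
simulated dataset is fitted under **both** prior regimes by default
(common random numbers), so family contrasts are not confounded by
simulation noise.  Sub-seeds for data generation and for each fit are a
pure function of (master seed, cell index, replicate index), which makes
runs reproducible, resumable and order-independent.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evaluation import ReplicationRecord, metric_table
from .mcmc import ChainSettings, FitResult, fit_model
from .priors import PriorRegime, canonical_regime
from .simulate import (
    PartiallyNestedDataset,
    SimulationCondition,
    TruthParameters,
    canonical_grid,
    generate_dataset,
)

__all__ = [
    "StudyConfig",
    "run_study",
    "recommend_prior",
    "recommendation_grid",
    "derive_seed",
    "scaled_settings",
]


def derive_seed(master_seed: int, *indices: int) -> int:
    """Stable 31-bit sub-seed from a master seed and an index path."""
    state = np.random.SeedSequence(
        entropy=master_seed, spawn_key=tuple(indices)
    ).generate_state(1, dtype=np.uint64)[0]
    return int(state % (2**31))


def scaled_settings(
    seed: int = 0,
    n_iter: int = 5000,
    n_burn: int = 1000,
    thin: int = 5,
    n_chains: int = 3,
) -> ChainSettings:
    """A desk-scale chain profile for tests and exploratory runs.

    This is deliberately shorter than the full long-chain protocol
    (50,000 iterations, 10,000 burn-in, thin 10) used for final study
    runs.
    """
    return ChainSettings(
        n_iter=n_iter, n_burn=n_burn, thin=thin, n_chains=n_chains, seed=seed
    )


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one Monte-Carlo study."""

    grid: Sequence[SimulationCondition] = field(default_factory=canonical_grid)
    n_reps: int = 1000
    chain_settings: ChainSettings = field(default_factory=ChainSettings)
    master_seed: int = 0
    truth: TruthParameters = field(default_factory=TruthParameters)
    output_dir: str | Path | None = None
    report_scale: float = 1.0
    common_random_numbers: bool = True
    regimes: dict | None = None  # family -> PriorRegime override

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def regime_for(self, family: str) -> PriorRegime:
        if self.regimes and family in self.regimes:
            return self.regimes[family]
        return canonical_regime(family)


def _cells(grid: Sequence[SimulationCondition]) -> list[tuple]:
    """Collapse the condition grid into design cells with their prior
    families, preserving first-seen order."""
    cells: dict[tuple, dict] = {}
    for cond in grid:
        key = (cond.c, cond.m, cond.rho, cond.n_control)
        entry = cells.setdefault(key, {"condition": cond, "families": []})
        if cond.prior_family not in entry["families"]:
            entry["families"].append(cond.prior_family)
    return [
        (idx, key, entry["families"])
        for idx, (key, entry) in enumerate(cells.items())
    ]


_FAMILY_STREAM = {"gamma": 1, "uniform": 2}


def _record_from_fit(
    condition: SimulationCondition,
    rep: int,
    truth: TruthParameters,
    fit: FitResult,
) -> ReplicationRecord:
    if not fit.converged:
        return ReplicationRecord(
            condition=condition, rep_id=rep, converged=False, truth=truth
        )
    b1 = fit.summary("b1")
    s2u = fit.summary("sigma2_U")
    return ReplicationRecord(
        condition=condition,
        rep_id=rep,
        converged=True,
        truth=truth,
        treatment_effect=b1.mean,
        treatment_effect_low=b1.ci_low,
        treatment_effect_high=b1.ci_high,
        nesting_effect=s2u.mean,
        nesting_effect_low=s2u.ci_low,
        nesting_effect_high=s2u.ci_high,
    )


def _log_line(
    condition: SimulationCondition,
    rep: int,
    seed: int,
    fit: FitResult | None,
    elapsed: float,
    error: str | None = None,
) -> dict:
    line = {
        "c": condition.c,
        "m": condition.m,
        "rho": condition.rho,
        "prior": condition.prior_family,
        "rep": rep,
        "seed": seed,
        "wall_time_s": round(elapsed, 4),
    }
    if error is not None:
        line.update(converged=False, error=error)
    else:
        line.update(
            converged=fit.converged,
            acceptance_rates={
                k: (None if v != v else round(v, 4))
                for k, v in fit.acceptance_rates.items()
            },
        )
    return line


def run_study(
    config: StudyConfig,
    progress: Callable[[str], None] | None = None,
) -> tuple[pd.DataFrame, list[ReplicationRecord]]:
    """Run the full study and return (metric table, replicate records).

    When ``config.output_dir`` is set, per-replicate summaries are
    appended to ``records.jsonl`` as they complete; a rerun with the same
    directory skips replicates already on disk, so interrupted studies
    resume where they stopped.  Fit failures are logged and counted as
    non-converged; they never abort the study.
    """
    out_dir: Path | None = None
    done: set[tuple] = set()
    existing_records: list[ReplicationRecord] = []
    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records_path = out_dir / "records.jsonl"
        if records_path.exists():
            for raw in records_path.read_text().splitlines():
                if not raw.strip():
                    continue
                payload = json.loads(raw)
                key = (
                    payload["c"],
                    payload["m"],
                    payload["rho"],
                    payload["prior"],
                    payload["rep"],
                )
                if key in done:
                    continue
                done.add(key)
                existing_records.append(_record_from_payload(payload, config))

    records: list[ReplicationRecord] = list(existing_records)
    for cell_idx, (c, m, rho, n_control), families in _cells(config.grid):
        base = SimulationCondition(
            c=c, m=m, rho=rho, n_control=n_control, prior_family=families[0]
        )
        for rep in range(config.n_reps):
            todo = [
                fam
                for fam in families
                if (c, m, rho, fam, rep) not in done
            ]
            if not todo:
                continue
            shared_dataset = None
            if config.common_random_numbers:
                data_seed = derive_seed(config.master_seed, cell_idx, rep, 0)
                shared_dataset = generate_dataset(base, config.truth, seed=data_seed)
            truth = dataclasses.replace(config.truth, rho=rho)
            for fam in families:
                if fam not in todo:
                    continue
                condition = dataclasses.replace(base, prior_family=fam)
                if config.common_random_numbers:
                    fit_data = shared_dataset
                else:
                    fam_seed = derive_seed(
                        config.master_seed, cell_idx, rep, 10 + _FAMILY_STREAM[fam]
                    )
                    fit_data = generate_dataset(base, config.truth, seed=fam_seed)
                fit_seed = derive_seed(
                    config.master_seed, cell_idx, rep, _FAMILY_STREAM[fam]
                )
                settings = dataclasses.replace(
                    config.chain_settings, seed=fit_seed
                )
                started = time.perf_counter()
                error = None
                fit = None
                try:
                    fit = fit_model(fit_data, config.regime_for(fam), settings)
                    record = _record_from_fit(condition, rep, truth, fit)
                except Exception as exc:  # noqa: BLE001 - never abort the study
                    error = f"{type(exc).__name__}: {exc}"
                    record = ReplicationRecord(
                        condition=condition,
                        rep_id=rep,
                        converged=False,
                        truth=truth,
                    )
                elapsed = time.perf_counter() - started
                records.append(record)
                if out_dir is not None:
                    line = _log_line(condition, rep, fit_seed, fit, elapsed, error)
                    line.update(_record_payload(record))
                    with (out_dir / "records.jsonl").open("a") as fh:
                        fh.write(json.dumps(line) + "\n")
            if progress is not None:
                progress(f"cell {cell_idx} (c={c}, m={m}, rho={rho}) rep {rep}")

    table = metric_table(records)
    if out_dir is not None:
        table.to_csv(out_dir / "metrics.csv", index=False)
    return table, records


def _record_payload(record: ReplicationRecord) -> dict:
    return {
        "treatment_effect": record.treatment_effect,
        "treatment_effect_low": record.treatment_effect_low,
        "treatment_effect_high": record.treatment_effect_high,
        "nesting_effect": record.nesting_effect,
        "nesting_effect_low": record.nesting_effect_low,
        "nesting_effect_high": record.nesting_effect_high,
    }


def _record_from_payload(payload: dict, config: StudyConfig) -> ReplicationRecord:
    condition = SimulationCondition(
        c=payload["c"],
        m=payload["m"],
        rho=payload["rho"],
        prior_family=payload["prior"],
    )
    truth = dataclasses.replace(config.truth, rho=payload["rho"])
    return ReplicationRecord(
        condition=condition,
        rep_id=payload["rep"],
        converged=payload["converged"],
        truth=truth,
        treatment_effect=payload.get("treatment_effect"),
        treatment_effect_low=payload.get("treatment_effect_low"),
        treatment_effect_high=payload.get("treatment_effect_high"),
        nesting_effect=payload.get("nesting_effect"),
        nesting_effect_low=payload.get("nesting_effect_low"),
        nesting_effect_high=payload.get("nesting_effect_high"),
    )


# ---------------------------------------------------------------------------
# prior recommendation


def _default_rule(metrics_g: dict, metrics_u: dict) -> str:
    """Smaller nesting-effect RMSE wins; ties broken by coverage distance
    from the nominal 95%, then by absolute bias."""
    for key, transform in (
        ("rmse", abs),
        ("coverage", lambda v: abs(v - 95.0)),
        ("bias", abs),
    ):
        g, u = transform(metrics_g[key]), transform(metrics_u[key])
        if g < u:
            return "G"
        if u < g:
            return "U"
    return "G"


def recommend_prior(
    table: pd.DataFrame,
    rule: Callable[[dict, dict], str] | str = "nesting_rmse",
) -> pd.DataFrame:
    """Per-cell G/U verdicts from a metric table covering both families.

    The default rule compares nesting-effect RMSE (coverage, then bias,
    as tie-breaks); pass a callable ``rule(metrics_gamma, metrics_uniform)
    -> "G" | "U"`` to plug in another adjudication.
    """
    if isinstance(rule, str):
        if rule != "nesting_rmse":
            raise ValueError(f"unknown recommendation rule {rule!r}")
        rule_fn = _default_rule
    else:
        rule_fn = rule

    nest = table[table["parameter"] == "nesting_effect"]
    rows = []
    for (c, m, rho), cell in nest.groupby(["c", "m", "rho"]):
        metrics = {}
        for fam, fam_rows in cell.groupby("prior"):
            metrics[fam] = dict(zip(fam_rows["metric"], fam_rows["value"]))
        if set(metrics) != {"gamma", "uniform"}:
            raise ValueError(
                f"cell (c={c}, m={m}, rho={rho}) lacks one prior family"
            )
        rows.append(
            {
                "c": c,
                "m": m,
                "rho": rho,
                "choice": rule_fn(metrics["gamma"], metrics["uniform"]),
            }
        )
    return pd.DataFrame(rows)


def recommendation_grid(recommendations: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-cell verdicts into an m-by-(rho, c) grid of G/U labels."""
    return recommendations.pivot_table(
        index="m",
        columns=["rho", "c"],
        values="choice",
        aggfunc="first",
    )
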