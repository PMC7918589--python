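"""End-to-end analysis: costing + QALYs + bootstrap + CEAC + sensitivity.

:func:`run_full_analysis` reads a trial cohort, attributes the deterministic
per-arm course cost to each patient, accrues QALYs after LOCF imputation,
runs the within-arm bootstrap and CEAC, computes the per-follow-up-week
probability-cost-effective series, and repeats the incremental analysis
under the overhead uplift (all direct costs × (1 + overhead_fraction); the
effect side is untouched, so ΔE is identical and ΔC scales exactly).

Every run writes a metadata JSON with the seed, replication count and a
configuration hash so each output row is traceable to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import reference
from .costing import (
    AmortizationScenario,
    CostModel,
    CourseCost,
    apply_overhead,
    course_cost,
    equipment_cost_per_session,
    round_euros,
)
from .eq5d import UtilityTrajectory, group_mean_table, locf_impute, qaly_auc
from .engine import (
    AverageIcer,
    BootstrapCloud,
    CEACCurve,
    CEResult,
    PatientOutcome,
    average_icer,
    bootstrap_ce,
    ce_plane_export,
    ceac,
    default_wtp_grid,
    incremental_analysis,
    prob_ce_series,
    quadrant_counts,
)
from .errors import ConfigError, DataError
from .io import load_cost_config, load_value_set, read_trial_csv

log = logging.getLogger("trialcea")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; echoed (hashed) into the metadata."""

    cohort_csv: str
    out_dir: str
    value_set: Optional[str] = None  # None: utilities precomputed in the CSV
    cost_config: Optional[str] = None  # None: reference cost model
    n_reps: int = 1000
    seed: int = 42
    wtp_max: float = 25_000.0
    wtp_step: float = 50.0
    series_lambda: float = 25_000.0
    overhead_fraction: float = 0.30
    make_plots: bool = False

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ResultBundle:
    cost_table: pd.DataFrame
    qol_table: pd.DataFrame
    ce_result: CEResult
    overhead_ce_result: CEResult
    cloud: BootstrapCloud
    ceac_curve: CEACCurve
    avg_icer: AverageIcer
    prob_by_week: pd.DataFrame
    metadata: dict


def _arm_cost_models(
    cfg: RunConfig,
) -> dict[str, tuple[CostModel, AmortizationScenario]]:
    if cfg.cost_config is None:
        m = dataclasses.replace(
            reference.REFERENCE_COSTS, overhead_fraction=cfg.overhead_fraction
        )
        return {
            "DN": (m, reference.DN_SCENARIO),
            "PNE": (m, reference.PNE_SCENARIO_PRINTED_INCREMENT),
        }
    model, pne_scenario = load_cost_config(cfg.cost_config)
    model = dataclasses.replace(model, overhead_fraction=cfg.overhead_fraction)
    return {
        "DN": (model, AmortizationScenario(kind="none", label="none")),
        "PNE": (model, pne_scenario),
    }


def build_cost_table(
    arm_models: Mapping[str, tuple[CostModel, AmortizationScenario]]
) -> tuple[pd.DataFrame, dict[str, CourseCost]]:
    """Per-arm cost breakdown mirroring the published cost-table rows."""
    rows, courses = [], {}
    for arm, (m, scen) in arm_models.items():
        equip = equipment_cost_per_session(m, scen)
        cc = course_cost(m, equip, arm=arm, scenario=scen.label or scen.kind)
        courses[arm] = cc
        rows.append(
            {
                "arm": arm,
                "scenario": cc.scenario,
                "consumables_per_session": m.consumables_per_session,
                "physio_per_session": m.physio_per_session,
                "physiatrist_per_session": m.physiatrist_per_session,
                "equipment_per_session": equip,
                "first_week_cost": cc.first_week_cost,
                "course_total": cc.course_total,
                "overhead_increment": cc.overhead_increment,
                "course_total_with_overhead": cc.course_total_with_overhead,
            }
        )
    return pd.DataFrame(rows), courses


def patient_outcomes(
    trajectories: Sequence[UtilityTrajectory],
    courses: Mapping[str, CourseCost],
    horizon_weeks: float = 52.0,
) -> list[PatientOutcome]:
    """LOCF-impute, accrue QALYs and attribute the arm course cost."""
    outcomes = []
    for t in trajectories:
        q = qaly_auc(locf_impute(t), horizon_weeks=horizon_weeks)
        outcomes.append(
            PatientOutcome(
                patient_id=t.patient_id,
                arm=t.arm,
                cost=courses[t.arm].course_total,
                qaly=q.total_qaly,
            )
        )
    return outcomes


def overhead_reanalysis(
    outcomes: Sequence[PatientOutcome], fraction: float
) -> CEResult:
    """Repeat the incremental analysis with every cost uplifted by the
    overhead fraction; QALYs are untouched."""
    uplifted = [
        dataclasses.replace(o, cost=apply_overhead(o.cost, fraction).total)
        for o in outcomes
    ]
    return incremental_analysis(uplifted)


def run_full_analysis(cfg: RunConfig) -> ResultBundle:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    vs = load_value_set(cfg.value_set) if cfg.value_set else None
    trajectories, excluded = read_trial_csv(cfg.cohort_csv, value_set=vs)
    if not trajectories:
        raise DataError("no analysable patients in the cohort")
    log.info("stage qaly: %d trajectories in, %d excluded", len(trajectories), len(excluded))

    arm_models = _arm_cost_models(cfg)
    cost_table, courses = build_cost_table(arm_models)
    imputed = [locf_impute(t) for t in trajectories]
    qol_table = group_mean_table(imputed)
    outcomes = patient_outcomes(trajectories, courses)

    point = incremental_analysis(outcomes)
    over = overhead_reanalysis(outcomes, cfg.overhead_fraction)
    cloud = bootstrap_ce(outcomes, n_reps=cfg.n_reps, seed=cfg.seed)
    curve = ceac(cloud, default_wtp_grid(cfg.wtp_max, cfg.wtp_step))
    avg = average_icer(cloud)
    if abs(point.delta_qaly) < 1e-3:
        log.warning(
            "averaged ICERs are unstable when the mean QALY difference is near "
            "zero (ΔE = %.5f); prefer the CEAC", point.delta_qaly
        )
    series = prob_ce_series(
        imputed,
        costs={o.patient_id: o.cost for o in outcomes},
        lam=cfg.series_lambda,
        n_reps=cfg.n_reps,
        seed=cfg.seed,
    )

    metadata = {
        "seed": cfg.seed,
        "n_reps": cfg.n_reps,
        "config": cfg.as_dict(),
        "config_hash": cfg.config_hash(),
        "n_patients": len(trajectories),
        "excluded_missing_baseline": excluded,
        "quadrant_counts": quadrant_counts(cloud),
    }
    bundle = ResultBundle(
        cost_table=cost_table,
        qol_table=qol_table,
        ce_result=point,
        overhead_ce_result=over,
        cloud=cloud,
        ceac_curve=curve,
        avg_icer=avg,
        prob_by_week=series,
        metadata=metadata,
    )
    _write_outputs(bundle, out, cfg)
    return bundle


def _fmt_costs(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(round_euros)
    return out


def _write_outputs(bundle: ResultBundle, out: Path, cfg: RunConfig) -> None:
    # published-table analogues: costs to 2 decimals, utilities to 3,
    # rounded here only — upstream objects keep full precision
    _fmt_costs(bundle.cost_table).to_csv(out / "cost_table.csv", index=False)
    bundle.qol_table.round(3).to_csv(out / "qol_table.csv", index=False)

    ce = bundle.ce_result
    over = bundle.overhead_ce_result
    pd.DataFrame(
        [
            {
                "analysis": "direct_costs",
                "delta_cost": round_euros(ce.delta_cost),
                "delta_qaly": round(ce.delta_qaly, 4),
                "icer": round_euros(ce.icer) if ce.icer is not None else "",
                "quadrant": ce.quadrant,
            },
            {
                "analysis": f"overhead_{cfg.overhead_fraction:.0%}",
                "delta_cost": round_euros(over.delta_cost),
                "delta_qaly": round(over.delta_qaly, 4),
                "icer": round_euros(over.icer) if over.icer is not None else "",
                "quadrant": over.quadrant,
            },
        ]
    ).to_csv(out / "ce_result.csv", index=False)

    ce_plane_export(bundle.cloud).round(6).to_csv(out / "bootstrap_pairs.csv", index=False)
    bundle.ceac_curve.to_frame().round(6).to_csv(out / "ceac.csv", index=False)
    bundle.prob_by_week.round(6).to_csv(out / "prob_by_week.csv", index=False)
    with open(out / "metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True)

    if cfg.make_plots:
        from . import plots

        plots.qol_plot(bundle.qol_table, out / "fig_qol.png")
        plots.ce_plane_plot(bundle.cloud, out / "fig_ce_plane.png")
        plots.ceac_plot(bundle.ceac_curve, out / "fig_ceac.png")
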