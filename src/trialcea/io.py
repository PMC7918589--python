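"""Reading and writing the package's delimited-text interfaces.

Trial CSV (long format)
    Columns ``patient_id, arm, week`` plus either the five EQ-5D dimension
    levels ``mo, sc, ua, pd, ad`` (integers 1–5) or a precomputed
    ``utility`` column; an empty cell marks a missing assessment.

Value-set CSV
    Either a full lookup (columns ``state, value``, 3125 rows) or additive
    decrement coefficients (columns ``term, value`` with terms mo2..ad5).

Cost configuration
    TOML, YAML or JSON with ``[costs]`` (unit costs) and ``[scenario]``
    (amortization) tables; see :func:`cost_config_from_dict`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .costing import AmortizationScenario, CostModel
from .eq5d import DIM_CODES, HealthState, UtilityTrajectory, ValueSet, apply_value_set
from .errors import ConfigError, DataError

log = logging.getLogger("trialcea")

_TRIAL_KEYS = ("patient_id", "arm", "week")


def load_value_set(path: str | Path, name: Optional[str] = None) -> ValueSet:
    """Load a value set, auto-detecting lookup vs coefficient layout."""
    path = Path(path)
    table = pd.read_csv(path)
    cols = set(table.columns)
    name = name or path.stem
    if {"state", "value"} <= cols:
        return ValueSet.from_lookup(name, table)
    if {"term", "value"} <= cols:
        return ValueSet.from_coefficients(
            name, dict(zip(table["term"].astype(str), table["value"].astype(float)))
        )
    raise ConfigError(
        f"{path}: value-set file needs either (state, value) or (term, value) columns"
    )


def packaged_value_set() -> ValueSet:
    """The bundled *synthetic* tariff (see ``data/synthetic_uk_like_valueset.csv``).

    A stand-in with realistic shape (anchor 1.0, floor −0.285, strictly
    monotone decrements) for tests and examples; it is NOT a published
    national value set and must not be used to score real study data.
    """
    return load_value_set(
        Path(__file__).parent / "data" / "synthetic_uk_like_valueset.csv",
        name="synthetic_uk_like",
    )


def read_trial_csv(
    path: str | Path,
    value_set: Optional[ValueSet] = None,
) -> tuple[list[UtilityTrajectory], list[str]]:
    """Read patient trajectories from a long-format trial CSV.

    Rows carrying the five dimension columns are scored with ``value_set``
    (required in that case); rows carrying ``utility`` are taken as-is.
    The assessment grid is the sorted union of weeks in the file; a patient
    missing a week (or with an empty value) is missing at that week.
    Patients with a missing baseline are excluded with a logged warning
    (LOCF, and hence the intention-to-treat analysis, has no origin for
    them); their ids are returned as the second element.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = set(_TRIAL_KEYS) - set(df.columns)
    if missing_cols:
        raise DataError(f"{path}: trial CSV lacks required columns {sorted(missing_cols)}")

    has_dims = set(DIM_CODES) <= set(df.columns)
    has_utility = "utility" in df.columns
    if not has_dims and not has_utility:
        raise DataError(
            f"{path}: trial CSV needs either a 'utility' column or the five "
            f"dimension columns {DIM_CODES}"
        )

    if has_utility:
        util = pd.to_numeric(df["utility"], errors="coerce")
    else:
        if value_set is None:
            raise ConfigError(
                f"{path}: dimension-level responses require a value set to score them"
            )
        util = pd.Series(np.nan, index=df.index, dtype=float)
        dims = df[list(DIM_CODES)].apply(pd.to_numeric, errors="coerce")
        complete = dims.notna().all(axis=1)
        for i in df.index[complete]:
            levels = [int(dims.at[i, c]) for c in DIM_CODES]
            util.at[i] = apply_value_set(HealthState(*levels), value_set)

    df = df.assign(_utility=util)
    weeks = tuple(sorted(df["week"].astype(float).unique()))
    if not weeks or weeks[0] != 0:
        raise DataError(f"{path}: the assessment grid must include week 0 (baseline)")

    trajectories: list[UtilityTrajectory] = []
    excluded: list[str] = []
    for (pid, arm), g in df.groupby(["patient_id", "arm"], sort=True):
        by_week = dict(zip(g["week"].astype(float), g["_utility"]))
        utilities = [by_week.get(w, np.nan) for w in weeks]
        if not np.isfinite(utilities[0]):
            excluded.append(str(pid))
            log.warning(
                "patient %s excluded: baseline (week 0) utility missing", pid
            )
            continue
        trajectories.append(
            UtilityTrajectory.build(str(pid), str(arm), weeks, utilities)
        )
    log.info(
        "read %s: %d patients kept, %d excluded (missing baseline)",
        path.name,
        len(trajectories),
        len(excluded),
    )
    return trajectories, excluded


def write_trial_csv(frame_or_trajectories, path: str | Path) -> None:
    """Write a cohort back out in the trial CSV dialect."""
    if isinstance(frame_or_trajectories, pd.DataFrame):
        frame = frame_or_trajectories
    else:
        rows = []
        for t in frame_or_trajectories:
            for w, u, obs in zip(t.weeks, t.utilities, t.observed):
                rows.append(
                    {
                        "patient_id": t.patient_id,
                        "arm": t.arm,
                        "week": w,
                        "utility": u if obs and np.isfinite(u) else None,
                    }
                )
        frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.6g")


def _load_structured(path: Path) -> dict:
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if suffix in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            return yaml.safe_load(fh)
    if suffix == ".json":
        with open(path) as fh:
            return json.load(fh)
    raise ConfigError(f"{path}: unsupported config format {suffix!r} (use TOML/YAML/JSON)")


def cost_config_from_dict(cfg: dict) -> tuple[CostModel, AmortizationScenario]:
    """Build a cost model and PNE amortization scenario from a config dict.

    Recognised keys: a ``costs`` table with any ``CostModel`` field, and a
    ``scenario`` table with any ``AmortizationScenario`` field (``kind``
    required). Unknown keys raise, so typos never silently fall back to
    defaults.
    """
    costs = dict(cfg.get("costs", {}))
    scenario = dict(cfg.get("scenario", {"kind": "none"}))
    unknown = set(cfg) - {"costs", "scenario"}
    if unknown:
        raise ConfigError(f"unknown top-level config sections {sorted(unknown)}")
    try:
        model = CostModel(**costs)
    except TypeError as exc:
        raise ConfigError(f"bad [costs] entry: {exc}") from None
    try:
        scen = AmortizationScenario(**scenario)
    except TypeError as exc:
        raise ConfigError(f"bad [scenario] entry: {exc}") from None
    return model, scen


def load_cost_config(path: str | Path) -> tuple[CostModel, AmortizationScenario]:
    return cost_config_from_dict(_load_structured(Path(path)))
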