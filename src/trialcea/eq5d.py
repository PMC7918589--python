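"""EQ-5D-5L utilities: health-state scoring, LOCF imputation and QALY AUC.

The EQ-5D-5L instrument describes a health state by five dimensions
(mobility, self-care, usual activities, pain/discomfort, anxiety/depression),
each graded 1 (no problems) to 5 (extreme problems), giving 5**5 = 3125
states coded as five-digit strings such as ``"21132"``. A *value set* maps
each state to a utility index anchored at 1 for full health (``"11111"``)
and 0 for dead; states worse than dead carry negative indices down to the
value set's floor.

Per-patient utility trajectories over a fixed assessment grid are imputed by
last observation carried forward (LOCF) and converted to quality-adjusted
life years (QALYs) by trapezoidal area under the curve, with 52 weeks
treated as one year so a 52-week horizon yields QALYs directly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BaselineMissingError,
    ConfigError,
    DataError,
    IncompleteTrajectoryError,
)

#: Dimension names in EQ-5D order, and their conventional two-letter codes.
DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
DIM_CODES = ("mo", "sc", "ua", "pd", "ad")

#: Assessment grid of the motivating trial (weeks after baseline).
ASSESSMENT_WEEKS = (0.0, 4.0, 8.0, 12.0, 26.0, 52.0)

#: Year convention: 52 weeks == 1 year.
WEEKS_PER_YEAR = 52.0

ARMS = ("DN", "PNE")


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-5L response: five severity levels, each in 1..5."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if not isinstance(level, (int, np.integer)) or not 1 <= level <= 5:
                raise DataError(
                    f"EQ-5D level for {dim!r} must be an integer in 1..5, got {level!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(int(getattr(self, dim)) for dim in DIMENSIONS)  # type: ignore[return-value]

    @property
    def code(self) -> str:
        """Five-digit state code, e.g. ``\"11111\"``."""
        return "".join(str(v) for v in self.levels)

    @classmethod
    def from_code(cls, code: str) -> "HealthState":
        code = str(code).strip()
        if len(code) != 5 or not code.isdigit():
            raise DataError(f"malformed EQ-5D-5L state code {code!r}")
        return cls(*(int(c) for c in code))


def all_state_codes() -> list[str]:
    """The 3125 EQ-5D-5L state codes in lexicographic order."""
    return ["".join(p) for p in itertools.product("12345", repeat=5)]


class ValueSet:
    """A tariff mapping every EQ-5D-5L state to a utility index.

    Built either from a full 3125-row lookup or from additive decrement
    coefficients (index = 1 − Σ decrement[dimension, level]). The anchor
    index of full health must be 1.0; the floor is the minimum index in the
    set. Weak monotonicity (worsening one dimension never raises the index)
    is validated with a warning, never an exception, because supplied tariff
    files are external data the package does not correct.
    """

    anchor: float = 1.0

    def __init__(self, name: str, values: Mapping[str, float]):
        self.name = name
        vals = {str(k): float(v) for k, v in values.items()}
        missing = 3125 - len(set(vals) & set(all_state_codes()))
        if missing:
            raise ConfigError(
                f"value set {name!r} does not resolve all 3125 states "
                f"({missing} missing)"
            )
        if not math.isclose(vals["11111"], 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"value set {name!r} must anchor full health '11111' at 1.0, "
                f"got {vals['11111']}"
            )
        above = [k for k, v in vals.items() if v > 1.0 + 1e-9]
        if above:
            warnings.warn(
                f"value set {name!r}: {len(above)} states exceed the full-health "
                f"anchor 1.0 (e.g. {above[0]})",
                stacklevel=2,
            )
        self._values = vals
        self.floor = min(vals.values())

    def index(self, state: "HealthState | str") -> float:
        """Utility index for a state (``HealthState`` or 5-digit code)."""
        code = state.code if isinstance(state, HealthState) else str(state).strip()
        if len(code) != 5 or any(c not in "12345" for c in code):
            # route through HealthState for a uniform malformed-input error
            code = HealthState.from_code(code).code
        try:
            return self._values[code]
        except KeyError:
            raise DataError(
                f"value set {self.name!r} has no entry for state {code!r}"
            ) from None

    __call__ = index

    def validate_monotone(self, warn: bool = True) -> list[tuple[str, str]]:
        """Check weak monotonicity; return (state, worsened-state) violations.

        Warns (does not raise) when the supplied tariff violates it.
        """
        violations: list[tuple[str, str]] = []
        for code in all_state_codes():
            v = self._values[code]
            for pos in range(5):
                lvl = int(code[pos])
                if lvl < 5:
                    worse = code[:pos] + str(lvl + 1) + code[pos + 1 :]
                    if self._values[worse] > v + 1e-12:
                        violations.append((code, worse))
        if violations and warn:
            warnings.warn(
                f"value set {self.name!r} violates weak monotonicity in "
                f"{len(violations)} state pairs (e.g. {violations[0]})",
                stacklevel=2,
            )
        return violations

    @classmethod
    def from_lookup(cls, name: str, table: pd.DataFrame) -> "ValueSet":
        """Build from a frame with columns ``state`` and ``value``."""
        if not {"state", "value"} <= set(table.columns):
            raise ConfigError("lookup value-set table needs 'state' and 'value' columns")
        states = table["state"].astype(str).str.strip().str.zfill(5)
        return cls(name, dict(zip(states, table["value"].astype(float))))

    @classmethod
    def from_coefficients(cls, name: str, coeffs: Mapping[str, float]) -> "ValueSet":
        """Build from additive decrements keyed ``mo2``..``ad5``.

        Level-1 terms are implicitly zero; index = 1 − Σ decrements.
        """
        dec = np.zeros((5, 6))  # [dimension, level]; level 0 unused
        for term, value in coeffs.items():
            t = str(term).strip().lower()
            if t in {"intercept", "constant"} and abs(float(value)) < 1e-12:
                continue
            if len(t) != 3 or t[:2] not in DIM_CODES or t[2] not in "2345":
                raise ConfigError(f"unrecognised value-set coefficient term {term!r}")
            dec[DIM_CODES.index(t[:2]), int(t[2])] = float(value)
        values = {
            code: 1.0 - sum(dec[d, int(code[d])] for d in range(5))
            for code in all_state_codes()
        }
        return cls(name, values)


def apply_value_set(state: "HealthState | str", vs: ValueSet) -> float:
    """Score one health state with a value set (pure lookup)."""
    return vs.index(state)


@dataclass(frozen=True)
class UtilityTrajectory:
    """A patient's utility index over the assessment grid.

    ``utilities`` holds NaN where an assessment is missing; ``observed``
    stays False at imputed points so they remain distinguishable after LOCF.
    """

    patient_id: str
    arm: str
    weeks: tuple[float, ...]
    utilities: tuple[float, ...]
    observed: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not (len(self.weeks) == len(self.utilities) == len(self.observed)):
            raise DataError(f"trajectory {self.patient_id}: ragged week/utility/flag lengths")
        if len(self.weeks) < 1 or self.weeks[0] != 0:
            raise DataError(f"trajectory {self.patient_id}: first week must be 0 (baseline)")
        if any(b >= a for a, b in zip(self.weeks[1:], self.weeks)):
            raise DataError(f"trajectory {self.patient_id}: weeks must be strictly increasing")
        for u, obs in zip(self.utilities, self.observed):
            if obs and not np.isfinite(u):
                raise DataError(
                    f"trajectory {self.patient_id}: observed flag set on a missing value"
                )
            if np.isfinite(u) and u > 1.0 + 1e-9:
                raise DataError(
                    f"trajectory {self.patient_id}: utility {u} exceeds the full-health anchor 1.0"
                )

    @classmethod
    def build(
        cls,
        patient_id: str,
        arm: str,
        weeks: Sequence[float],
        utilities: Sequence[float],
        observed: Sequence[bool] | None = None,
    ) -> "UtilityTrajectory":
        u = tuple(float(x) if x is not None else math.nan for x in utilities)
        obs = (
            tuple(bool(b) for b in observed)
            if observed is not None
            else tuple(bool(np.isfinite(x)) for x in u)
        )
        return cls(str(patient_id), arm, tuple(float(w) for w in weeks), u, obs)

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.utilities)))

    @property
    def baseline(self) -> float:
        return self.utilities[0]


def locf_impute(t: UtilityTrajectory) -> UtilityTrajectory:
    """Fill missing follow-ups with the most recent earlier value.

    Baseline must be present (the intention-to-treat origin); observed flags
    are preserved, so imputed points remain flagged unobserved. Idempotent.
    """
    if not np.isfinite(t.utilities[0]):
        raise BaselineMissingError(
            f"patient {t.patient_id}: baseline utility missing; cannot carry forward"
        )
    filled: list[float] = []
    last = t.utilities[0]
    for u in t.utilities:
        if np.isfinite(u):
            last = u
        filled.append(last)
    return replace(t, utilities=tuple(filled))


@dataclass(frozen=True)
class QalyResult:
    """QALYs over the horizon, plus the gain over a flat-baseline trajectory.

    ``baseline_anchored_gain`` subtracts the baseline utility held constant
    over the horizon, isolating accrual beyond the patient's starting state.
    """

    patient_id: str
    total_qaly: float
    baseline_anchored_gain: float
    horizon_weeks: float


def qaly_auc(t: UtilityTrajectory, horizon_weeks: float = 52.0) -> QalyResult:
    """Trapezoidal QALY area under the utility curve.

    ``horizon_weeks`` must be one of the trajectory's assessment weeks
    (normally the last, 52); utility-weeks are divided by 52 weeks/year.
    The trajectory must be complete up to the horizon (run LOCF first).
    """
    weeks = np.asarray(t.weeks, dtype=float)
    if horizon_weeks not in t.weeks:
        raise ConfigError(
            f"horizon {horizon_weeks} is not an assessment week of patient {t.patient_id}"
        )
    mask = weeks <= horizon_weeks
    u = np.asarray(t.utilities, dtype=float)[mask]
    if not np.all(np.isfinite(u)):
        raise IncompleteTrajectoryError(
            f"patient {t.patient_id}: missing utilities before week {horizon_weeks}; "
            "impute (LOCF) before computing QALYs"
        )
    area = float(np.trapezoid(u, weeks[mask]))
    horizon_years = horizon_weeks / WEEKS_PER_YEAR
    total = area / WEEKS_PER_YEAR
    return QalyResult(
        patient_id=t.patient_id,
        total_qaly=total,
        baseline_anchored_gain=total - u[0] * horizon_years,
        horizon_weeks=float(horizon_weeks),
    )


def _sd(x: np.ndarray) -> float:
    # sample SD; a single observation has no dispersion, reported as 0
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def group_mean_table(trajectories: Iterable[UtilityTrajectory]) -> pd.DataFrame:
    """Per-week descriptive table: arm means, SDs, change from baseline and
    the between-arm (PNE − DN) difference.

    Missing values are excluded per cell; run LOCF first for an
    intention-to-treat table.
    """
    ts = list(trajectories)
    by_arm: dict[str, list[UtilityTrajectory]] = {a: [] for a in ARMS}
    for t in ts:
        by_arm[t.arm].append(t)
    for arm, group in by_arm.items():
        if not group:
            raise DataError(f"group_mean_table: arm {arm!r} is empty")
    grids = {t.weeks for t in ts}
    if len(grids) != 1:
        raise DataError("group_mean_table: trajectories are on different assessment grids")
    weeks = np.asarray(next(iter(grids)), dtype=float)

    cols: dict[str, np.ndarray] = {"week": weeks}
    for arm in ARMS:
        mat = np.array([t.utilities for t in by_arm[arm]], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            mean = np.nanmean(mat, axis=0)
        sd = np.array(
            [_sd(col[np.isfinite(col)]) for col in mat.T]
        )
        cols[f"mean_{arm}"] = mean
        cols[f"sd_{arm}"] = sd
        cols[f"change_{arm}"] = mean - mean[0]
    cols["diff_PNE_minus_DN"] = cols["mean_PNE"] - cols["mean_DN"]
    cols["sd_diff"] = np.sqrt(cols["sd_PNE"] ** 2 + cols["sd_DN"] ** 2)
    return pd.DataFrame(cols)
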