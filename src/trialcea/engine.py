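"""Incremental cost-effectiveness analysis and probabilistic sensitivity.

Given per-patient (cost, QALY) outcomes for two trial arms, this module
computes the point incremental analysis (ΔC, ΔE, ICER, dominance quadrant),
a nonparametric bootstrap of the cost–QALY pairs (patients resampled with
replacement independently within each arm, arm sizes fixed — the standard
scheme for a two-arm randomized trial, preserving the randomization
structure), the cost-effectiveness acceptability curve (CEAC) over a grid of
willingness-to-pay thresholds λ, and the per-follow-up-week probability of
being cost-effective on truncated QALY horizons.

Conventions
-----------
* Deltas are comparator-minus-reference; here PNE − DN.
* A bootstrap pair is cost-effective at λ when its incremental net benefit
  λ·ΔE − ΔC is strictly positive: a tie (INB exactly 0) counts as not
  cost-effective.
* Cost-effectiveness plane quadrants split on the signs of (ΔC, ΔE), with
  zero ΔC classed as "not costlier" and zero ΔE as "not more effective":
  NE (costlier, more effective), SE (cheaper, more effective — dominant),
  NW (costlier, less effective — dominated), SW (cheaper, less effective).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .eq5d import UtilityTrajectory, qaly_auc
from .errors import ConfigError, DataError

ARMS = ("DN", "PNE")
QUADRANTS = ("NE", "SE", "NW", "SW")

#: Default willingness-to-pay grid: 0 to €25,000/QALY in €50 steps — the
#: conventional adoption-threshold ceiling in the reference setting.
DEFAULT_WTP_MAX = 25_000.0
DEFAULT_WTP_STEP = 50.0


def default_wtp_grid(
    wtp_max: float = DEFAULT_WTP_MAX, step: float = DEFAULT_WTP_STEP
) -> np.ndarray:
    return np.arange(0.0, wtp_max + step / 2, step)


@dataclass(frozen=True)
class PatientOutcome:
    """One patient's attributed course cost (euros) and accrued QALYs."""

    patient_id: str
    arm: str
    cost: float
    qaly: float

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.cost < 0:
            raise DataError(f"patient {self.patient_id}: negative cost {self.cost}")


def quadrant_of(delta_cost: float, delta_qaly: float) -> str:
    if delta_qaly > 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


@dataclass(frozen=True)
class CEResult:
    """Point incremental analysis (comparator − reference arm means)."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    quadrant: str
    mean_cost: Mapping[str, float]
    mean_qaly: Mapping[str, float]
    n: Mapping[str, int]

    @property
    def dominant(self) -> bool:
        """Comparator cheaper and more effective."""
        return self.quadrant == "SE"

    @property
    def dominated(self) -> bool:
        return self.quadrant == "NW"


def _split_arms(
    outcomes: Iterable[PatientOutcome],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_arm: dict[str, list[PatientOutcome]] = {a: [] for a in ARMS}
    for o in outcomes:
        by_arm[o.arm].append(o)
    for arm, group in by_arm.items():
        if not group:
            raise DataError(f"arm {arm!r} has no patients")
    return {
        arm: (
            np.array([o.cost for o in group], dtype=float),
            np.array([o.qaly for o in group], dtype=float),
        )
        for arm, group in by_arm.items()
    }


def incremental_analysis(outcomes: Iterable[PatientOutcome]) -> CEResult:
    """Arm means, PNE − DN deltas, ICER (ΔC/ΔE) and plane quadrant.

    When ΔE is exactly 0 the ICER is undefined and returned as None; no
    division is attempted.
    """
    arms = _split_arms(outcomes)
    mean_cost = {a: float(np.mean(c)) for a, (c, _) in arms.items()}
    mean_qaly = {a: float(np.mean(q)) for a, (_, q) in arms.items()}
    dc = mean_cost["PNE"] - mean_cost["DN"]
    de = mean_qaly["PNE"] - mean_qaly["DN"]
    icer = dc / de if de != 0 else None
    return CEResult(
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        quadrant=quadrant_of(dc, de),
        mean_cost=mean_cost,
        mean_qaly=mean_qaly,
        n={a: len(c) for a, (c, _) in arms.items()},
    )


@dataclass(frozen=True)
class BootstrapCloud:
    """Resampled (ΔC, ΔE) pairs from within-arm bootstrap of patients."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_reps: int
    seed: Optional[int]
    arm_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.delta_cost) != self.n_reps or len(self.delta_qaly) != self.n_reps:
            raise ConfigError("bootstrap cloud must hold exactly n_reps pairs")


def bootstrap_ce(
    outcomes: Iterable[PatientOutcome],
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> BootstrapCloud:
    """Nonparametric bootstrap of the cost–QALY pairs.

    Each replicate resamples patients with replacement independently within
    each arm (arm sizes preserved; arms never mix), recomputes the arm mean
    cost and mean QALY, and stores the PNE − DN deltas. Bit-reproducible for
    a fixed seed: one generator, arms drawn in fixed (DN, PNE) order.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be at least 1")
    arms = _split_arms(outcomes)
    rng = np.random.default_rng(seed)
    means: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for arm in ARMS:  # fixed draw order for reproducibility
        cost, qaly = arms[arm]
        idx = rng.integers(0, len(cost), size=(n_reps, len(cost)))
        means[arm] = (cost[idx].mean(axis=1), qaly[idx].mean(axis=1))
    return BootstrapCloud(
        delta_cost=means["PNE"][0] - means["DN"][0],
        delta_qaly=means["PNE"][1] - means["DN"][1],
        n_reps=n_reps,
        seed=seed,
        arm_sizes={a: len(arms[a][0]) for a in ARMS},
    )


@dataclass(frozen=True)
class CEACCurve:
    """Probability cost-effective as a function of willingness to pay λ."""

    thresholds: np.ndarray
    probability: np.ndarray

    def at(self, lam: float) -> float:
        """Probability at a threshold present in the grid."""
        hits = np.flatnonzero(np.isclose(self.thresholds, lam))
        if hits.size == 0:
            raise ConfigError(f"threshold {lam} is not on the CEAC grid")
        return float(self.probability[hits[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp_threshold": self.thresholds, "prob_cost_effective": self.probability}
        )


def prob_cost_effective(cloud: BootstrapCloud, lam: float) -> float:
    """Fraction of bootstrap pairs with strictly positive INB at λ."""
    if lam < 0:
        raise ConfigError("willingness-to-pay threshold must be non-negative")
    return float(np.mean(lam * cloud.delta_qaly - cloud.delta_cost > 0))


def ceac(cloud: BootstrapCloud, thresholds: Optional[Sequence[float]] = None) -> CEACCurve:
    """Cost-effectiveness acceptability curve over a λ grid.

    For each λ the probability is the fraction of pairs with
    λ·ΔE − ΔC > 0 (ties count as not cost-effective).
    """
    lam = np.asarray(default_wtp_grid() if thresholds is None else thresholds, dtype=float)
    if lam.size == 0:
        raise ConfigError("empty threshold grid")
    if np.any(lam < 0):
        raise ConfigError("willingness-to-pay thresholds must be non-negative")
    inb = lam[:, None] * cloud.delta_qaly[None, :] - cloud.delta_cost[None, :]
    return CEACCurve(thresholds=lam, probability=(inb > 0).mean(axis=1))


@dataclass(frozen=True)
class AverageIcer:
    """Mean of per-replicate ICERs over same-sign (NE/SW) quadrants.

    Averaged ICERs are numerically unstable when replicate ΔE values come
    close to zero; interpret alongside the ratio-of-means ICER, never alone.
    """

    value: Optional[float]
    n_used: int
    n_reps: int

    @property
    def fraction_used(self) -> float:
        return self.n_used / self.n_reps if self.n_reps else 0.0


def average_icer(cloud: BootstrapCloud) -> AverageIcer:
    """Average the per-replicate ratio ΔC/ΔE over replicates where the ratio
    has its conventional meaning (NE: costlier & more effective, SW: cheaper
    & less effective)."""
    dc, de = cloud.delta_cost, cloud.delta_qaly
    mask = ((dc > 0) & (de > 0)) | ((dc < 0) & (de < 0))
    n = int(mask.sum())
    value = float(np.mean(dc[mask] / de[mask])) if n else None
    return AverageIcer(value=value, n_used=n, n_reps=cloud.n_reps)


def ce_plane_export(cloud: BootstrapCloud) -> pd.DataFrame:
    """Plot-ready table of (ΔE, ΔC) pairs with plane-quadrant labels."""
    quad = np.where(
        cloud.delta_qaly > 0,
        np.where(cloud.delta_cost > 0, "NE", "SE"),
        np.where(cloud.delta_cost > 0, "NW", "SW"),
    )
    return pd.DataFrame(
        {
            "delta_qaly": cloud.delta_qaly,
            "delta_cost": cloud.delta_cost,
            "quadrant": quad,
        }
    )


def quadrant_counts(cloud: BootstrapCloud) -> dict[str, int]:
    """Exhaustive quadrant tally; counts always sum to n_reps."""
    table = ce_plane_export(cloud)["quadrant"].value_counts()
    return {q: int(table.get(q, 0)) for q in QUADRANTS}


def prob_ce_series(
    trajectories: Iterable[UtilityTrajectory],
    costs: Mapping[str, float],
    weeks: Optional[Sequence[float]] = None,
    lam: float = DEFAULT_WTP_MAX,
    n_reps: int = 1000,
    seed: Optional[int] = None,
    costs_by_week: Optional[Mapping[float, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Probability cost-effective at λ for each follow-up horizon.

    For each follow-up week t, per-patient QALYs are recomputed on the
    truncated horizon [0, t], the within-arm bootstrap is re-run, and the
    CEAC probability at λ is reported. By default the full course cost is
    attributed at every horizon (``costs`` maps patient_id → course cost);
    pass ``costs_by_week`` (week → patient_id → accrued cost) to attribute
    costs accrued to date instead — for a course of weekly sessions the two
    coincide from the first follow-up onward.

    Each horizon's bootstrap uses an independent child seed spawned from
    ``seed``, so the series is reproducible as a whole.
    """
    ts = list(trajectories)
    if not ts:
        raise DataError("no trajectories supplied")
    grid = ts[0].weeks
    if weeks is None:
        weeks = [w for w in grid if w > 0]
    for w in weeks:
        if w not in grid or w == 0:
            raise ConfigError(
                f"week {w} is not a follow-up assessment week of the grid {grid}"
            )
    if lam < 0:
        raise ConfigError("willingness-to-pay threshold must be non-negative")

    children = np.random.SeedSequence(seed).spawn(len(list(weeks)))
    rows = []
    for w, child in zip(weeks, children):
        week_costs = costs_by_week[w] if costs_by_week is not None else costs
        outcomes = [
            PatientOutcome(
                patient_id=t.patient_id,
                arm=t.arm,
                cost=float(week_costs[t.patient_id]),
                qaly=qaly_auc(t, horizon_weeks=w).total_qaly,
            )
            for t in ts
        ]
        cloud = bootstrap_ce(
            outcomes, n_reps=n_reps, seed=int(child.generate_state(1)[0] % 2**31)
        )
        point = incremental_analysis(outcomes)
        rows.append(
            {
                "week": w,
                "prob_cost_effective": prob_cost_effective(cloud, lam),
                "delta_cost": point.delta_cost,
                "delta_qaly": point.delta_qaly,
            }
        )
    return pd.DataFrame(rows)
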