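"""Session and course costing with equipment amortization and overhead uplift.

A treatment course is four weekly needling sessions. Each session costs the
physiotherapist's time plus sanitary consumables; the physiatrist's
supervision visit is charged once, in the first week, and by the published
convention is reported in the first-week figure but excluded from the
four-session course total (switchable via ``include_physiatrist_in_course``).
The electrolysis arm additionally carries a per-session share of the
equipment purchase price under one of two amortization scenarios:

``study_sessions``
    the full price spread over the sessions delivered in the trial
    (price / n_sessions), the pessimistic single-study view;
``clinic_amortized``
    the price spread over a standard clinic's annual usage across an
    amortization period (price / (uses_per_year × years));
``none``
    no equipment (the dry-needling arm).

Overhead (indirect facility costs) enters as a single fractional uplift on
direct costs, up to 30% in the reference analysis.

All arithmetic is carried out in integer milli-euros (0.1 cent), so unit
costs specified to sub-cent precision stay exact; rounding to whole cents
happens only at the reporting boundary (:func:`round_euros`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional

from .errors import ConfigError

_MILLS = 1000  # milli-euros per euro


def _to_mills(euros: float) -> int:
    return int(round(float(euros) * _MILLS))


def _to_euros(mills: int) -> float:
    return mills / _MILLS


def round_euros(x: float) -> float:
    """Round to whole cents for reporting (2 decimals, half away from zero)."""
    import math

    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CostModel:
    """Unit costs (euros) and course structure.

    Defaults reproduce the reference trial's published cost table;
    consumables are stored at sub-cent precision (1.065) because the
    published course total 178.86 = 4 × (43.65 + 1.065) is only consistent
    with a sub-cent consumables figure printed as 1.06.
    """

    consumables_per_session: float = 1.065
    physio_per_session: float = 43.65
    physiatrist_per_session: float = 96.03
    equipment_price: float = 2300.0
    n_sessions_per_course: int = 4
    overhead_fraction: float = 0.30
    include_physiatrist_in_course: bool = False

    def __post_init__(self) -> None:
        for name in (
            "consumables_per_session",
            "physio_per_session",
            "physiatrist_per_session",
            "equipment_price",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_sessions_per_course < 0:
            raise ConfigError("n_sessions_per_course must be non-negative")
        if not 0.0 <= self.overhead_fraction <= 1.0:
            raise ConfigError("overhead_fraction must lie in [0, 1]")


AmortKind = Literal["study_sessions", "clinic_amortized", "none"]


@dataclass(frozen=True)
class AmortizationScenario:
    """How the equipment purchase price becomes a per-session cost.

    ``per_session_override`` short-circuits the formula; it exists because
    published per-session equipment figures do not always equal the stated
    formula applied to the stated inputs, and reproducing a published table
    then requires the printed value.
    """

    kind: AmortKind
    study_sessions: int = 204
    uses_per_year: int = 816
    amortization_years: int = 3
    per_session_override: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("study_sessions", "clinic_amortized", "none"):
            raise ConfigError(f"unknown amortization kind {self.kind!r}")


class OverheadResult(NamedTuple):
    increment: float
    total: float


class ScenarioBand(NamedTuple):
    low: float
    high: float
    midpoint: float
    half_range: float


@dataclass(frozen=True)
class CourseCost:
    """Costs of one full treatment course for one arm under one scenario."""

    arm: str
    scenario: str
    first_week_cost: float
    course_total: float
    course_total_with_overhead: float
    overhead_increment: float
    equipment_per_session: float


def equipment_cost_per_session(m: CostModel, s: AmortizationScenario) -> float:
    """Per-session equipment cost (euros) under an amortization scenario."""
    if s.per_session_override is not None:
        if s.per_session_override < 0:
            raise ConfigError("per_session_override must be non-negative")
        return float(s.per_session_override)
    if s.kind == "none":
        return 0.0
    if s.kind == "study_sessions":
        if s.study_sessions <= 0:
            raise ConfigError("study_sessions must be positive")
        return m.equipment_price / s.study_sessions
    if s.uses_per_year <= 0 or s.amortization_years <= 0:
        raise ConfigError("uses_per_year and amortization_years must be positive")
    return m.equipment_price / (s.uses_per_year * s.amortization_years)


def _cents_half_even(mills: int) -> int:
    # exact decimal rounding of milli-euros to whole cents, ties to even
    q, r = divmod(mills, 10)
    if r > 5 or (r == 5 and q % 2 == 1):
        q += 1
    return q


def first_week_cost(m: CostModel, equipment_per_session: float) -> float:
    """Cost of the first treatment week: physiatrist + physio + consumables
    + equipment share (the physiatrist visit is charged in week 1 only).

    Follows the display convention of published cost tables: each unit cost
    is rounded to whole cents before summing, so a sub-cent consumables
    figure enters this row at its printed value.
    """
    cents = (
        _cents_half_even(_to_mills(m.physiatrist_per_session))
        + _cents_half_even(_to_mills(m.physio_per_session))
        + _cents_half_even(_to_mills(m.consumables_per_session))
        + _cents_half_even(_to_mills(equipment_per_session))
    )
    return cents / 100.0


def apply_overhead(cost: float, fraction: float) -> OverheadResult:
    """Uplift a direct cost by a fixed overhead fraction.

    Returns both the increment (cost × fraction) and the uplifted total.
    Only the single-uplift form is defined: uplifting by f1 then f2 is not
    the same as uplifting once by f1 + f2.
    """
    if fraction < 0:
        raise ConfigError("overhead fraction must be non-negative")
    c = _to_mills(cost)
    inc = int(round(c * fraction))
    return OverheadResult(_to_euros(inc), _to_euros(c + inc))


def course_cost(
    m: CostModel,
    equipment_per_session: float,
    arm: str = "",
    scenario: str = "",
) -> CourseCost:
    """Total cost of a course of ``n_sessions_per_course`` sessions.

    ``course_total`` covers physio + consumables + equipment per session,
    times the number of sessions; the physiatrist visit is included only if
    ``m.include_physiatrist_in_course`` (default off, matching the published
    convention where it appears in the first-week figure only).
    """
    per_session = (
        _to_mills(m.physio_per_session)
        + _to_mills(m.consumables_per_session)
        + _to_mills(equipment_per_session)
    )
    total = per_session * m.n_sessions_per_course
    if m.include_physiatrist_in_course and m.n_sessions_per_course > 0:
        total += _to_mills(m.physiatrist_per_session)
    inc, tot_oh = apply_overhead(_to_euros(total), m.overhead_fraction)
    return CourseCost(
        arm=arm,
        scenario=scenario,
        first_week_cost=first_week_cost(m, equipment_per_session),
        course_total=_to_euros(total),
        course_total_with_overhead=tot_oh,
        overhead_increment=inc,
        equipment_per_session=float(equipment_per_session),
    )


def scenario_band(a: CourseCost, b: CourseCost) -> ScenarioBand:
    """Summarise two equipment scenarios for the same arm as a cost band:
    (min, max, midpoint, half-range) of the course totals."""
    if a.arm != b.arm:
        raise ConfigError(
            f"scenario_band compares scenarios of one arm, got {a.arm!r} and {b.arm!r}"
        )
    lo, hi = sorted((a.course_total, b.course_total))
    return ScenarioBand(lo, hi, (lo + hi) / 2.0, (hi - lo) / 2.0)
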