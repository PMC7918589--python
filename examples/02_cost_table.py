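"""Reproduce the per-arm cost table: sessions, amortization, overhead.

Dry needling (DN) needs no equipment; percutaneous needle electrolysis
(PNE) adds a per-session share of the €2300 device under two amortization
scenarios, and a 30% overhead uplift represents indirect facility costs.
"""

import trialcea as t
from trialcea import reference as R

m = R.REFERENCE_COSTS
print(f"unit costs/session: physio €{m.physio_per_session}, "
      f"consumables €{m.consumables_per_session}, "
      f"physiatrist (week 1 only) €{m.physiatrist_per_session}")

for label, scen in [
    ("study sessions (2300/204)", R.PNE_SCENARIO_STUDY),
    ("clinic amortized (2300/(816*3))", R.PNE_SCENARIO_CLINIC),
]:
    e = t.equipment_cost_per_session(m, scen)
    print(f"PNE equipment per session, {label}: €{t.round_euros(e):.2f}")

dn = t.course_cost(m, 0.0, arm="DN")
pne = t.course_cost(m, R.PNE_EQUIPMENT_PER_SESSION_PRINTED_INCREMENT, arm="PNE")
print(f"\nDN : first week €{dn.first_week_cost:.2f}, "
      f"course €{t.round_euros(dn.course_total):.2f}, "
      f"+30% overhead €{t.round_euros(dn.course_total_with_overhead):.2f}")
print(f"PNE: first week €{pne.first_week_cost:.2f}, "
      f"course €{t.round_euros(pne.course_total):.2f}, "
      f"+30% overhead €{t.round_euros(pne.course_total_with_overhead):.2f}")
print(f"PNE incremental course cost: "
      f"€{t.round_euros(pne.course_total - dn.course_total):.2f}")

band = t.scenario_band(
    t.course_cost(m, t.equipment_cost_per_session(m, R.PNE_SCENARIO_CLINIC), arm="PNE"),
    t.course_cost(m, R.PNE_EQUIPMENT_PER_SESSION_STUDY_PRINTED, arm="PNE"),
)
print(f"PNE course across equipment scenarios: €{band.low:.2f}–€{band.high:.2f} "
      f"(midpoint €{band.midpoint:.2f} ± €{band.half_range:.2f})")
# The band shows how much the equipment-costing assumption alone moves the
# course price; all other cost components are protocol-fixed.
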