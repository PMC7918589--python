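"""Score EQ-5D-5L states with a value set and turn a trajectory into QALYs.

Builds one patient by hand: a painful baseline, improvement by week 4,
missing later visits filled by last observation carried forward, and the
trapezoidal QALY area under the curve over the 52-week year.
"""

import trialcea as t

vs = t.packaged_value_set()  # synthetic tariff bundled for demonstrations
print(f"value set '{vs.name}': anchor 1.0, floor {vs.floor:.3f}")
for code in ("11111", "21341", "55555"):
    print(f"  state {code} -> utility {t.apply_value_set(code, vs):.3f}")

traj = t.UtilityTrajectory.build(
    patient_id="demo-01",
    arm="DN",
    weeks=(0, 4, 8, 12, 26, 52),
    utilities=[
        t.apply_value_set("21341", vs),  # baseline: moderate pain
        t.apply_value_set("11121", vs),  # week 4: nearly recovered
        None, None,                      # weeks 8 and 12 missed
        t.apply_value_set("11231", vs),  # week 26: partial relapse
        None,                            # week 52 missed
    ],
)
imputed = t.locf_impute(traj)
print("\nweek:     ", traj.weeks)
print("observed: ", traj.observed)
print("imputed:  ", tuple(round(u, 3) for u in imputed.utilities))

res = t.qaly_auc(imputed)
print(f"\ntotal QALYs over 52 weeks: {res.total_qaly:.3f}")
print(f"gain over flat baseline:   {res.baseline_anchored_gain:+.3f}")
# total_qaly is time lived weighted by utility (1 year of full health = 1.0);
# the gain isolates accrual beyond the patient's starting health state.
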