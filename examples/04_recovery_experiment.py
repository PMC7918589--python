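"""Check the pipeline's statistical calibration by simulation.

Repeatedly generates cohorts with a known true QALY difference (the
closed-form clamped-normal trapezoid of the generator), runs the bootstrap
on each, and measures bias of the ΔQALY estimate and empirical coverage of
the 2.5–97.5 percentile interval. Dropout is off so the analytic truth is
exactly the generated population's estimand.
"""

import dataclasses

import trialcea as t

spec = dataclasses.replace(t.CohortSpec(), dropout_hazard=0.0)
report = t.recovery_experiment(spec, n_sims=200, reps_per_sim=500, seed=2024)

print(f"true ΔQALY (analytic): {report.true_delta_qaly:.4f}")
print(f"mean estimate:         {report.estimates.mean():.4f} "
      f"(bias {report.bias:+.4f})")
print(f"95% interval coverage: {report.coverage:.1%} over {report.n_sims} trials")
print(f"mean P(cost-effective at €{report.lam:,.0f}/QALY): "
      f"{report.mean_ceac_prob:.2f}")
# Coverage near 95% and negligible bias mean the bootstrap intervals can be
# trusted at this sample size (51/arm); with dropout switched on, the same
# report instead quantifies the distortion LOCF imputation introduces.
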