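# trialcea

Trial-based cost-utility analysis for two-arm interventions, built around a
published comparison of dry needling (DN) and percutaneous needle
electrolysis (PNE) for plantar heel pain: EQ-5D-5L utility scoring, LOCF
imputation, QALY area-under-curve, session-level costing with equipment
amortization and overhead uplift, nonparametric bootstrap of cost–QALY
pairs, and cost-effectiveness acceptability curves (CEAC). A calibrated
synthetic-cohort generator stands in for the trial's unavailable
patient-level records, so the whole pipeline is testable end to end.

Intended users: health economists and trialists who want a transparent,
scriptable implementation of the standard trial-based CEA toolchain —
every convention (year length, tie rules, rounding, resampling scheme) is
explicit and tested.

## The model

For each patient, EQ-5D-5L responses at weeks 0, 4, 8, 12, 26 and 52 are
mapped to utilities *u(t)* by a value set (tariff), missing follow-ups are
filled by last observation carried forward, and QALYs are the trapezoidal
area under the curve with 52 weeks ≡ 1 year:

    QALY = (1/52) · Σ ½ (u(tᵢ) + u(tᵢ₊₁)) (tᵢ₊₁ − tᵢ)

Costs per arm are protocol-driven: four weekly sessions of physiotherapy
plus consumables, a first-week physiatrist visit, and for PNE a per-session
share of the €2300 device under an amortization scenario; overhead enters
as a 30% uplift on direct costs. The incremental analysis reports

    ΔC = C̄_PNE − C̄_DN,   ΔE = Ē_PNE − Ē_DN,   ICER = ΔC / ΔE,

bootstraps patients within arms (1000 replicates) for the
cost-effectiveness plane, and summarises decision uncertainty as
CEAC(λ) = P(λ·ΔE − ΔC > 0) across willingness-to-pay thresholds λ up to
€25,000/QALY. See `docs/methods.md` for conventions and assumptions.

## Worked example

```python
import trialcea as t

cohort = t.generate_cohort(t.CohortSpec(), seed=42)   # 51 patients/arm
bundle = t.run_full_analysis(t.RunConfig(
    cohort_csv="cohort.csv", out_dir="results", seed=42,
))
```

Running `python examples/03_full_cea.py` (which does exactly this) prints:

```
ΔC = €22.04, ΔE = 0.0146 QALY (quadrant NE)
ICER (ratio of means): €1508.39/QALY
average per-replicate ICER (NE/SW, 699/1000 reps): €1699.11/QALY — unstable when ΔE ≈ 0, prefer the CEAC
P(cost-effective at €25,000/QALY): 0.69
with 30% overhead: ΔC = €28.65, ICER €1960.91/QALY (ΔE unchanged: 0.0146)
```

Read: this simulated cohort happened to draw a small utility advantage for
PNE (ΔE = 0.0146 QALYs; the generator's true value is 0.066), so PNE costs
€22.04 more and buys extra QALYs at €1508 each — far below the €25,000
threshold, hence a 69% probability of being cost-effective. The overhead
re-analysis rescales only costs (ΔC × 1.30); the effect side is untouched.
The weekly series in `bundle.prob_by_week` shows the probability climbing
as the utility advantage accumulates toward week 52.

Other examples: `01_score_and_qalys.py` (value-set scoring, LOCF, AUC),
`02_cost_table.py` (the per-arm cost table and equipment-scenario band),
`04_recovery_experiment.py` (bootstrap interval calibration by simulation).

A thin CLI wraps the same functions:

```sh
trialcea simulate --seed 7 --out cohort.csv
trialcea run --input cohort.csv --reps 1000 --seed 42 --out results/
trialcea score --input dims.csv --value-set vs.csv --out scored.csv
trialcea report --cloud results/bootstrap_pairs.csv --out rerender/
```

## File formats

* **Trial CSV** (long format): columns `patient_id, arm, week`, then either
  the five dimension levels `mo, sc, ua, pd, ad` (integers 1–5) or a
  precomputed `utility` float; empty cell = missing assessment.
* **Value set**: CSV with `state,value` (3125 rows) or additive decrements
  `term,value` (terms `mo2`…`ad5`). The bundled
  `data/synthetic_uk_like_valueset.csv` is a synthetic demonstration
  tariff, not a published national value set.
* **Cost config**: TOML/YAML/JSON with `[costs]` (any `CostModel` field)
  and `[scenario]` (amortization) tables.

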