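# Methods

## Setting and estimands

`trialcea` implements a trial-based cost-utility analysis comparing two
needling interventions for plantar heel pain — dry needling (DN) and
percutaneous needle electrolysis (PNE) — from a hospital perspective over a
52-week horizon. Effectiveness is the quality-adjusted life year (QALY)
accrued from EQ-5D-5L utility trajectories; costs are the direct costs of a
four-session treatment course. The headline outputs are the incremental
cost ΔC and incremental effect ΔE (PNE − DN arm means), the incremental
cost-effectiveness ratio ICER = ΔC/ΔE, the bootstrap cloud of (ΔE, ΔC)
pairs on the cost-effectiveness plane, and the cost-effectiveness
acceptability curve CEAC(λ) = P(λ·ΔE − ΔC > 0) over willingness-to-pay
thresholds λ.

## Utilities and QALYs

Health states are the 3125 five-digit EQ-5D-5L codes; a *value set* maps
each to a utility index anchored at 1 for `11111`, with negative values
(worse than dead) permitted down to the set's floor. Value sets are
consumed as data — either a full 3125-row lookup or additive per-level
decrements — never re-estimated; loading validates the anchor exactly and
checks weak monotonicity with a warning rather than an error, since a
supplied tariff is external evidence the package must not silently repair.
The bundled `synthetic_uk_like` file is a constructed stand-in with
realistic shape (floor −0.285, strictly monotone); it exists for tests and
examples and must not score real study data.

Missing follow-ups are imputed by last observation carried forward (LOCF),
the intention-to-treat convention of the source analysis. LOCF requires an
observed baseline; patients without one are excluded with a logged warning
rather than silently dropped, because carry-forward has no origin for them.
Observed/imputed flags are preserved so downstream summaries can audit the
imputation. Utilities are never truncated or winsorized by the analysis
code: anything in [floor, 1] is legal.

QALYs are the trapezoidal area under the utility–time curve on the
(0, 4, 8, 12, 26, 52)-week grid, divided by 52 weeks/year — the package
adopts 52 weeks ≡ 1 year throughout, so the 52-week horizon yields QALYs
directly and every printed week count stays transparent in the arithmetic.
Two per-patient summaries are reported: `total_qaly` (the AUC itself, used
for all incremental analysis) and `baseline_anchored_gain` (AUC minus the
baseline utility held flat over the horizon). Both are standard; reporting
both brackets the conventions encountered in published summaries, whose
printed per-arm "QALY gains" cannot always be reconstructed from group-mean
trajectories under either convention alone.

## Costing

All currency arithmetic runs in integer milli-euros (0.1 cent); rounding to
whole cents happens only at the reporting boundary. This keeps the sub-cent
consumables price (€1.065/session) exact: the published course total
178.86 = 4 × (43.65 + 1.065) requires it, while the published first-week
row is the sum of the *cent-rounded* unit costs (96.03 + 43.65 + 1.06 =
140.74). `first_week_cost` therefore rounds each unit cost to cents
(ties to even) before summing; course totals use full precision. The
physiatrist's supervision visit is charged once, in week 1, and excluded
from the four-session course total — the convention the published totals
imply — switchable via `include_physiatrist_in_course`.

Equipment amortization offers two scenarios: the device price spread over
the study's 204 sessions (2300/204 = €11.27/session) or over a standard
clinic's use (2300/(816 × 3) ≈ €0.94/session; the 816 annual uses are
back-solved from the published €0.94 at 3-year amortization and exposed as
an overridable assumption). Published per-session figures that disagree
with their own formula (€12.21 for the study scenario) and the published
incremental course cost (€22.04, i.e. €5.51/session) are available as
`per_session_override` values in `trialcea.reference`, so both the
formula path and the printed-figures path can be reproduced; the
printed-increment scenario is the pipeline default because every published
downstream number (200.90, 261.17, the overhead ICER) derives from it.
`scenario_band` summarises the two equipment scenarios as min/max/midpoint
± half-range of the course totals.

Overhead (indirect facility cost) is a single fractional uplift on direct
costs, 0.30 by default; only the single-uplift form cost × (1 + f) is
defined — composing two uplifts is deliberately not equivalent to their
sum, and nothing assumes it is.

## Incremental analysis and uncertainty

The bootstrap resamples patients with replacement independently within each
arm, arm sizes fixed — the standard scheme for a two-arm randomized trial,
preserving the randomization structure; arms never mix. One seeded
generator drives each run (arms drawn in fixed DN-then-PNE order), making
clouds bit-reproducible; the seed is echoed in the run metadata.

The CEAC counts a replicate cost-effective at λ only when its incremental
net benefit λ·ΔE − ΔC is strictly positive; a tie counts as not
cost-effective. The convention is documented rather than inferred — with
continuous costs it is negligible. The default λ grid is €0–25,000/QALY in
€50 steps, the conventional adoption-threshold ceiling in the reference
setting. Plane quadrants split on the signs of (ΔC, ΔE) with zeros classed
as "not costlier"/"not more effective", so counts are exhaustive and
conserve the replicate count.

Two ICER summaries are computed. The ratio-of-means ICER is the primary
one. The *average* ICER — the mean of per-replicate ΔC/ΔE over replicates
in the same-sign (NE/SW) quadrants, where the ratio retains its
conventional meaning — is reported alongside because published summaries
sometimes quote it, with an explicit warning: it is numerically unstable
whenever replicate ΔE values approach zero, and the CEAC should be
preferred.

The per-week series recomputes per-patient QALYs on each truncated horizon
[0, t] for follow-up weeks t, re-runs the bootstrap (independent child
seeds spawned per week) and reports the CEAC probability at λ. Full course
costs are attributed at every horizon by default; accrued-to-date
attribution is available via `costs_by_week`, though for a course of four
weekly sessions the two coincide from the first follow-up (week 4) onward.

## Synthetic cohort generator

No patient-level data accompany the source analysis, so the generator is
the package's test bed. Its defaults *are* the study conditions: 51
patients per arm, the published per-arm/per-week utility means and SDs,
course costs €178.86 (DN) and €200.90 (PNE). Utility at week t is
mean + √f·sd·b_i + √(1−f)·sd·e_it with standard-normal patient effect b_i
and occasion noise e_it, so every cell's variance matches the published SD
exactly and within-patient correlation arises solely from the shared random
effect — no autoregressive structure, since no longitudinal correlation is
published. The variance split f defaults to 0.5 and is configurable, as is
an explicit per-cell (between, occasion) SD decomposition, validated
against the totals. Draws are clamped to [floor, 1]; pre-clamp draws are
retained and the mean shift due to clamping is reported
(`Cohort.truncation_bias`), so calibration checks can separate clamping
from the noise model. A Gaussian-with-clamping model was chosen over a beta
or copula model because only means and SDs are published — it is the
simplest model matching them.

Dropout is monotone and non-informative: at each follow-up visit a
still-active patient stops with hazard 0.05 (the source reports a high
dropout rate without quantifying it; 5%/visit ≈ 23% cumulative loss over
five follow-ups is a realistic attrition level for a year of follow-up, and
the value is clearly an assumption, not a published figure). A
hazard-depending-on-utility extension would slot into `generate_cohort`
where the per-visit Bernoulli draws are made, but informative missingness
is deliberately out of scope.

What passing tests on this generator do **not** show about real data: real
EQ-5D utilities are discrete (3125 tariff values), skewed and ceiling-heavy
rather than clamped-Gaussian; real dropout is plausibly informative; and
real costs can vary by patient. Results on the generator validate the
pipeline's arithmetic and statistical calibration, not clinical
conclusions.

## Calibration experiments

`recovery_experiment` repeatedly generates cohorts, runs the full pipeline
and scores it against the generator's analytic estimand. That estimand is
the trapezoid over *closed-form clamped-normal* cell means (each cell's
marginal is N(mean, sd) clipped to [floor, 1]; E[clip] has a standard
normal-distribution expression), which is exact when dropout is off. The
coverage experiment therefore runs with hazard 0: with dropout on, LOCF
carry-forward shifts the estimand (early, typically better post-treatment
values are carried into later weeks) and coverage of the analytic number
would measure that bias rather than interval calibration — with dropout the
report's bias column quantifies exactly that distortion instead. At the
study conditions (200 simulated trials, 500 bootstrap replicates each) the
2.5–97.5 percentile interval covers the true ΔQALY ≈ 94–96% of the time
with bias below half a percent of a QALY; percentile intervals at n = 51
per arm are expected to sit slightly below nominal.

Problem sizes used by the test suite and the acceptance script — 20 seeds ×
1000 replicates for the weekly probability series, 200 × 500 for coverage,
50,000 replicates for the law-of-large-numbers check — were chosen so each
Monte-Carlo standard error is comfortably below the quantity being
resolved; all complete in seconds because the bootstrap is vectorized over
replicates.

## Numerical and degenerate-input choices

* Trapezoid integration is `numpy.trapezoid` on the week grid; a dense
  piecewise-linear oracle agrees to 1e-9 in tests.
* Sample SDs use ddof = 1; a single observation reports SD 0 (no
  dispersion) rather than NaN.
* The between-group SD column of the descriptive table is the independence
  combination √(sd₁² + sd₂²); published difference SDs may follow other
  conventions and are not targeted.
* ΔE = 0 leaves the ICER undefined (`None`) and flagged — never a division.
* `qaly_auc` on an incomplete trajectory raises rather than integrating
  observed points only, forcing the imputation step to be explicit.
* Empty arms, non-grid horizon weeks, negative λ, zero amortization
  divisors and infeasible variance splits all raise typed errors
  (`DataError` vs `ConfigError`, CLI exit codes 1 vs 2).

## Known limitations

Indirect/societal costs, discounting (single-year horizon), comparison with
usual care, parametric sensitivity analysis beyond the overhead uplift, and
confidence ellipses on the CE plane are out of scope. Published headline
QALY gains and the published average ICER depend on patient-level data that
are not deposited; the package reproduces every desk-checkable figure to
the cent and brackets the rest with explicitly labelled conventions.
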