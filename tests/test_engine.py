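"""Incremental analysis, bootstrap cloud, CEAC and the weekly series."""

import numpy as np
import pytest

import trialcea as t
from trialcea.engine import AverageIcer, average_icer, quadrant_of
from trialcea.errors import ConfigError, DataError

from conftest import make_outcomes


def _cloud(dc, de):
    dc = np.asarray(dc, float)
    return t.BootstrapCloud(
        delta_cost=dc,
        delta_qaly=np.asarray(de, float),
        n_reps=len(dc),
        seed=None,
        arm_sizes={"DN": 1, "PNE": 1},
    )


# ------------------------------------------------------ incremental analysis


def test_icer_ratio_of_means_reproduces_overhead_example():
    outcomes = make_outcomes(dn=[(232.52, 0.300)], pne=[(261.17, 0.354)])
    res = t.incremental_analysis(outcomes)
    assert res.delta_cost == pytest.approx(28.65, abs=1e-9)
    assert res.delta_qaly == pytest.approx(0.054, abs=1e-9)
    assert res.icer == pytest.approx(530.6, abs=0.1)
    assert res.quadrant == "NE"


def test_icer_from_printed_course_increment():
    outcomes = make_outcomes(dn=[(178.86, 0.300)], pne=[(200.90, 0.354)])
    res = t.incremental_analysis(outcomes)
    assert res.icer == pytest.approx(22.04 / 0.054, abs=1e-6)  # ≈ 408.1


def test_dominant_comparator_is_flagged():
    outcomes = make_outcomes(dn=[(100.0, 0.50)], pne=[(95.0, 0.55)])
    res = t.incremental_analysis(outcomes)
    assert res.quadrant == "SE" and res.dominant and not res.dominated


def test_zero_delta_qaly_leaves_icer_undefined():
    outcomes = make_outcomes(dn=[(100.0, 0.5)], pne=[(120.0, 0.5)])
    res = t.incremental_analysis(outcomes)
    assert res.icer is None
    assert res.quadrant == "NW"  # zero ΔE counts as "not more effective"


def test_single_arm_input_is_an_error():
    with pytest.raises(DataError):
        t.incremental_analysis(make_outcomes(dn=[(1.0, 0.1)], pne=[]))


@pytest.mark.parametrize(
    "dc, de, expected",
    [(1, 1, "NE"), (-1, 1, "SE"), (1, -1, "NW"), (-1, -1, "SW"), (0, 1, "SE"), (1, 0, "NW")],
)
def test_quadrant_sign_convention(dc, de, expected):
    assert quadrant_of(dc, de) == expected


# ------------------------------------------------------------------ bootstrap


def test_bootstrap_is_reproducible_for_a_seed(small_cohort):
    a = t.bootstrap_ce(small_cohort.outcomes, n_reps=200, seed=5)
    b = t.bootstrap_ce(small_cohort.outcomes, n_reps=200, seed=5)
    assert np.array_equal(a.delta_cost, b.delta_cost)
    assert np.array_equal(a.delta_qaly, b.delta_qaly)
    c = t.bootstrap_ce(small_cohort.outcomes, n_reps=200, seed=6)
    assert not np.array_equal(a.delta_qaly, c.delta_qaly)


def test_zero_variance_arms_collapse_to_point_estimate():
    outcomes = make_outcomes(
        dn=[(178.86, 0.60)] * 5, pne=[(200.90, 0.70)] * 5
    )
    cloud = t.bootstrap_ce(outcomes, n_reps=100, seed=1)
    assert np.allclose(cloud.delta_cost, 22.04)
    assert np.allclose(cloud.delta_qaly, 0.10)


def test_bootstrap_mean_agrees_with_point_estimate(small_cohort):
    """Law of large numbers: the cloud mean converges on the sample deltas."""
    point = t.incremental_analysis(small_cohort.outcomes)
    cloud = t.bootstrap_ce(small_cohort.outcomes, n_reps=50_000, seed=9)
    for got, ref in (
        (cloud.delta_qaly, point.delta_qaly),
        (cloud.delta_cost, point.delta_cost),
    ):
        mc_se = got.std(ddof=1) / np.sqrt(cloud.n_reps)
        assert abs(got.mean() - ref) <= max(3 * mc_se, 1e-12)


def test_bootstrap_preserves_arm_sizes(small_cohort):
    cloud = t.bootstrap_ce(small_cohort.outcomes, n_reps=10, seed=0)
    assert cloud.arm_sizes == {"DN": 51, "PNE": 51}


def test_bootstrap_rejects_bad_rep_count(small_cohort):
    with pytest.raises(ConfigError):
        t.bootstrap_ce(small_cohort.outcomes, n_reps=0, seed=1)


# ----------------------------------------------------------------------- CEAC


def test_ceac_threshold_crossing_and_strict_tie_rule():
    cloud = _cloud([10.0] * 8, [0.1] * 8)
    curve = t.ceac(cloud, thresholds=[50.0, 100.0, 200.0])
    assert curve.at(50.0) == 0.0  # INB = 5 − 10 < 0
    assert curve.at(100.0) == 0.0  # INB = 0: tie counts as not cost-effective
    assert curve.at(200.0) == 1.0  # INB = 20 − 10 > 0


def test_half_dominant_half_dominated_cloud_sits_at_one_half():
    # brute-force oracle: count INB > 0 by hand at each λ
    dc = np.array([-5.0] * 10 + [5.0] * 10)
    de = np.array([0.05] * 10 + [-0.05] * 10)
    cloud = _cloud(dc, de)
    for lam in (1.0, 100.0, 10_000.0):
        expected = np.mean(lam * de - dc > 0)
        assert expected == 0.5
        assert t.prob_cost_effective(cloud, lam) == 0.5


def test_ceac_limits_match_quadrant_fractions(rng):
    dc = rng.normal(20, 30, size=500)
    de = rng.normal(0.02, 0.05, size=500)
    de = de[de != 0]
    cloud = _cloud(dc[: len(de)], de)
    assert t.prob_cost_effective(cloud, 0.0) == np.mean(cloud.delta_cost < 0)
    positive = cloud.delta_qaly > 0
    lam_star = 1.0 + np.max(np.abs(cloud.delta_cost / cloud.delta_qaly))
    assert t.prob_cost_effective(cloud, lam_star) == np.mean(positive)


def test_negative_threshold_rejected():
    cloud = _cloud([1.0], [0.1])
    with pytest.raises(ConfigError):
        t.ceac(cloud, thresholds=[-5.0])


# --------------------------------------------------------------- average ICER


def test_average_icer_uses_same_sign_quadrants_only():
    dc = np.array([10.0, 30.0, -10.0, 10.0, -10.0])
    de = np.array([0.1, 0.1, -0.1, -0.1, 0.1])  # NE, NE, SW, NW, SE
    got = average_icer(_cloud(dc, de))
    assert got.n_used == 3
    assert got.value == pytest.approx(np.mean([100.0, 300.0, 100.0]))


def test_average_icer_empty_mask_returns_none():
    got = average_icer(_cloud([-5.0], [0.1]))
    assert got.value is None and got.n_used == 0


# ------------------------------------------------------------------- CE plane


def test_quadrant_counts_conserved_and_match_recount(rng):
    dc = rng.normal(0, 30, size=1000)
    de = rng.normal(0, 0.05, size=1000)
    cloud = _cloud(dc, de)
    table = t.ce_plane_export(cloud)
    assert len(table) == 1000
    counts = t.quadrant_counts(cloud)
    assert sum(counts.values()) == 1000
    # independent recount
    assert counts["SE"] == int(np.sum((dc <= 0) & (de > 0)))
    assert counts["NE"] == int(np.sum((dc > 0) & (de > 0)))


def test_all_dominant_cloud_is_pure_se():
    counts = t.quadrant_counts(_cloud([-1.0] * 20, [0.1] * 20))
    assert counts == {"NE": 0, "SE": 20, "NW": 0, "SW": 0}


# -------------------------------------------------------------- weekly series


def _flat_trajectories(dn_level, pne_level, n=8):
    ts = []
    for arm, level in (("DN", dn_level), ("PNE", pne_level)):
        for i in range(n):
            ts.append(
                t.UtilityTrajectory.build(
                    f"{arm}{i}", arm, (0, 4, 8, 12, 26, 52), [level] * 6
                )
            )
    return ts


def test_dominant_arm_is_cost_effective_at_every_week():
    ts = _flat_trajectories(0.5, 0.8)
    costs = {tr.patient_id: (100.0 if tr.arm == "PNE" else 150.0) for tr in ts}
    series = t.prob_ce_series(ts, costs, lam=25_000.0, n_reps=200, seed=3)
    assert (series["prob_cost_effective"] == 1.0).all()
    assert list(series["week"]) == [4, 8, 12, 26, 52]


def test_identical_arms_hover_near_one_half():
    spec = t.CohortSpec(
        means={"DN": t.CohortSpec().means["DN"], "PNE": t.CohortSpec().means["DN"]},
        sds={"DN": t.CohortSpec().sds["DN"], "PNE": t.CohortSpec().sds["DN"]},
        costs={"DN": 178.86, "PNE": 178.86},
        dropout_hazard=0.0,
    )
    probs = []
    for seed in range(12):
        cohort = t.generate_cohort(spec, seed=seed)
        cloud = t.bootstrap_ce(cohort.outcomes, n_reps=400, seed=seed + 1000)
        probs.append(t.prob_cost_effective(cloud, 25_000.0))
    assert abs(np.mean(probs) - 0.5) < 0.15


def test_non_assessment_week_rejected():
    ts = _flat_trajectories(0.5, 0.6, n=2)
    costs = {tr.patient_id: 10.0 for tr in ts}
    with pytest.raises(ConfigError):
        t.prob_ce_series(ts, costs, weeks=[5], n_reps=10, seed=1)
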