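"""Health-state scoring, LOCF imputation and QALY area-under-curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trialcea as t
from trialcea.eq5d import ASSESSMENT_WEEKS, all_state_codes
from trialcea.errors import (
    BaselineMissingError,
    ConfigError,
    DataError,
    IncompleteTrajectoryError,
)

WEEKS = list(ASSESSMENT_WEEKS)

# ------------------------------------------------------------ health states


@pytest.mark.parametrize("code", ["11111", "55555", "21453", "12345"])
def test_health_state_code_round_trips(code):
    assert t.HealthState.from_code(code).code == code


@pytest.mark.parametrize("bad", ["1111", "111111", "11161", "1111a", "01111"])
def test_malformed_state_codes_rejected(bad):
    with pytest.raises(DataError):
        t.HealthState.from_code(bad)


def test_out_of_range_level_rejected():
    with pytest.raises(DataError):
        t.HealthState(1, 1, 1, 0, 1)


# ---------------------------------------------------------------- value set


def test_full_health_anchor_scores_one(value_set):
    assert t.apply_value_set("11111", value_set) == 1.0


def test_worst_state_scores_file_floor(value_set):
    # independent oracle: recompute the floor directly from the shipped
    # coefficient file rather than through the ValueSet machinery
    import trialcea.io as io_mod
    from pathlib import Path

    raw = pd.read_csv(
        Path(io_mod.__file__).parent / "data" / "synthetic_uk_like_valueset.csv"
    )
    worst_decrement = (
        raw.assign(level=raw["term"].str[2].astype(int))
        .loc[lambda d: d["level"] == 5, "value"]
        .sum()
    )
    assert t.apply_value_set("55555", value_set) == pytest.approx(
        1.0 - worst_decrement, abs=1e-12
    )
    assert value_set.floor == pytest.approx(1.0 - worst_decrement, abs=1e-12)


def test_any_single_worsening_scores_below_anchor(value_set):
    for pos in range(5):
        code = "11111"[:pos] + "2" + "11111"[pos + 1 :]
        assert t.apply_value_set(code, value_set) < 1.0


def test_all_states_bounded_and_anchor_unique(value_set):
    values = {code: value_set.index(code) for code in all_state_codes()}
    assert len(values) == 3125
    assert max(values.values()) == 1.0
    assert all(v <= 1.0 for v in values.values())
    assert [c for c, v in values.items() if v == 1.0] == ["11111"]
    assert min(values.values()) == value_set.floor


def test_shipped_value_set_is_monotone(value_set):
    assert value_set.validate_monotone(warn=False) == []


def test_non_monotone_lookup_warns_not_raises(value_set):
    values = {code: value_set.index(code) for code in all_state_codes()}
    values["21111"] = 1.0 - 1e-6
    values["31111"] = 1.0 - 1e-7  # better than the milder state: violation
    vs = t.ValueSet("broken", values)
    with pytest.warns(UserWarning, match="monotonicity"):
        violations = vs.validate_monotone()
    assert ("21111", "31111") in violations


def test_incomplete_lookup_rejected():
    with pytest.raises(ConfigError, match="3125"):
        t.ValueSet("partial", {"11111": 1.0, "55555": -0.2})


def test_coefficient_and_lookup_paths_agree(value_set):
    lookup = pd.DataFrame(
        {"state": all_state_codes(), "value": [value_set.index(c) for c in all_state_codes()]}
    )
    vs2 = t.ValueSet.from_lookup("same", lookup)
    for code in ("11111", "32541", "55555"):
        assert vs2.index(code) == pytest.approx(value_set.index(code), abs=1e-12)


# --------------------------------------------------------------------- LOCF


def _traj(utilities, arm="DN", observed=None):
    return t.UtilityTrajectory.build("p1", arm, WEEKS, utilities, observed)


def test_locf_carries_last_observation_forward():
    out = t.locf_impute(_traj([0.6, 0.8, None, None, None, None]))
    assert out.utilities == (0.6, 0.8, 0.8, 0.8, 0.8, 0.8)
    assert out.observed == (True, True, False, False, False, False)


def test_locf_fully_observed_is_identity():
    traj = _traj([0.6, 0.8, 0.7, 0.6, 0.5, 0.4])
    assert t.locf_impute(traj) == traj


def test_locf_missing_baseline_is_exclusion_error():
    with pytest.raises(BaselineMissingError):
        t.locf_impute(_traj([None, 0.8, 0.7, 0.6, 0.5, 0.4]))


@given(
    utilities=st.lists(
        st.floats(min_value=-0.285, max_value=1.0, allow_nan=False), min_size=6, max_size=6
    ),
    missing=st.sets(st.integers(min_value=1, max_value=5)),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_locf_idempotent_and_preserves_observed(utilities, missing):
    vals = [None if i in missing else u for i, u in enumerate(utilities)]
    traj = _traj(vals)
    once = t.locf_impute(traj)
    assert once.is_complete
    assert t.locf_impute(once) == once
    for i, (orig, new) in enumerate(zip(traj.utilities, once.utilities)):
        if traj.observed[i]:
            assert new == orig
    assert once.observed == traj.observed


# ---------------------------------------------------------------- QALY AUC


def test_constant_full_health_year_is_one_qaly():
    res = t.qaly_auc(_traj([1.0] * 6))
    assert res.total_qaly == pytest.approx(1.0, abs=1e-12)
    assert res.baseline_anchored_gain == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "arm, expected_utility_weeks",
    [
        # hand trapezoid on the published group means:
        # DN  2.814 + 2.996 + 2.724 + 8.995 + 16.952 = 34.481
        # PNE 2.852 + 2.988 + 2.862 + 9.912 + 19.318 = 37.932
        ("DN", 34.481),
        ("PNE", 37.932),
    ],
)
def test_group_mean_trajectory_qalys_match_hand_trapezoid(
    mean_trajectories, arm, expected_utility_weeks
):
    traj = next(tr for tr in mean_trajectories if tr.arm == arm)
    res = t.qaly_auc(traj, horizon_weeks=52)
    assert res.total_qaly == pytest.approx(expected_utility_weeks / 52.0, abs=1e-9)


def test_incomplete_trajectory_must_be_imputed_first():
    with pytest.raises(IncompleteTrajectoryError):
        t.qaly_auc(_traj([0.6, None, 0.7, 0.6, 0.5, 0.4]))


def test_horizon_must_be_an_assessment_week():
    with pytest.raises(ConfigError):
        t.qaly_auc(_traj([0.5] * 6), horizon_weeks=30)


def test_truncated_horizon_integrates_prefix_only():
    res = t.qaly_auc(_traj([0.5, 0.7, None, None, None, None]), horizon_weeks=4)
    assert res.total_qaly == pytest.approx(0.6 * 4 / 52, abs=1e-12)


@given(
    utilities=st.lists(
        st.floats(min_value=-0.285, max_value=1.0, allow_nan=False), min_size=6, max_size=6
    )
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_trapezoid_matches_dense_grid_integration(utilities):
    traj = _traj(utilities)
    res = t.qaly_auc(traj)
    grid = np.arange(0.0, 52.0 + 1e-9, 0.1)
    dense = np.trapezoid(np.interp(grid, WEEKS, utilities), grid) / 52.0
    assert res.total_qaly == pytest.approx(dense, abs=1e-9)
    # bounds for any valid 52-week trajectory
    assert -0.285 - 1e-12 <= res.total_qaly <= 1.0 + 1e-12


def test_constant_trajectory_gain_is_zero():
    res = t.qaly_auc(_traj([0.42] * 6))
    assert res.total_qaly == pytest.approx(0.42, abs=1e-12)
    assert res.baseline_anchored_gain == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------- descriptive table


def test_group_table_reproduces_between_group_differences(mean_trajectories):
    table = t.group_mean_table(mean_trajectories).set_index("week")
    diffs = table["diff_PNE_minus_DN"]
    assert diffs.loc[0] == pytest.approx(0.039, abs=1e-9)
    assert diffs.loc[12] == pytest.approx(0.053, abs=1e-9)
    assert table.loc[4, "change_DN"] == pytest.approx(0.147, abs=1e-9)


def test_single_identical_patient_per_arm_gives_zero_sds():
    utilities = [0.5, 0.6, 0.7, 0.6, 0.5, 0.4]
    table = t.group_mean_table(
        [_traj(utilities, arm="DN"), t.UtilityTrajectory.build("p2", "PNE", WEEKS, utilities)]
    )
    assert (table["diff_PNE_minus_DN"] == 0).all()
    assert (table["sd_DN"] == 0).all() and (table["sd_PNE"] == 0).all()


def test_empty_arm_is_an_error():
    with pytest.raises(DataError, match="empty"):
        t.group_mean_table([_traj([0.5] * 6, arm="DN")])
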