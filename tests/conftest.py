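import numpy as np
import pytest

import trialcea as t
from trialcea.reference import group_mean_trajectories


@pytest.fixture(scope="session")
def value_set() -> t.ValueSet:
    return t.packaged_value_set()


@pytest.fixture(scope="session")
def mean_trajectories():
    """One zero-variance trajectory per arm, pinned at the published group means."""
    return group_mean_trajectories()


@pytest.fixture(scope="session")
def small_cohort():
    """A reproducible calibrated cohort at the study conditions (51/arm)."""
    return t.generate_cohort(t.CohortSpec(), seed=20240)


@pytest.fixture()
def cohort_csv(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    t.write_trial_csv(small_cohort.frame, path)
    return path


def make_outcomes(dn, pne):
    """Build PatientOutcome lists from [(cost, qaly), ...] per arm."""
    out = []
    for arm, rows in (("DN", dn), ("PNE", pne)):
        for i, (cost, qaly) in enumerate(rows):
            out.append(
                t.PatientOutcome(patient_id=f"{arm}{i}", arm=arm, cost=cost, qaly=qaly)
            )
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
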