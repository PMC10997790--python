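import numpy as np
import pandas as pd
import pytest

from gosepred.cohort import COHORT_COLUMNS, Cohort
from gosepred.synthetic import profile_config, simulate_cohort


def make_cohort(rows, name="test"):
    """Build a Cohort from a list of (id, age, gcsm, pupils, marshall, gose)."""
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    frame["gcs_motor"] = pd.array(frame["gcs_motor"], dtype="Int64")
    frame["gose"] = pd.array(frame["gose"], dtype="Int64")
    frame["age"] = pd.array(frame["age"], dtype="Float64")
    return Cohort(data=frame, name=name)


@pytest.fixture
def small_cohort():
    return make_cohort(
        [
            ("a", 25.0, 6, "both", "diffuse_II", 8),
            ("b", 40.0, 3, "one", "diffuse_III", 3),
            ("c", 63.0, 1, "none", "evacuated_mass", 1),
            ("d", 55.0, 5, "both", "diffuse_I", 7),
            ("e", 78.0, 4, "both", "non_evacuated_mass", 5),
        ]
    )


@pytest.fixture
def missing_cohort():
    return make_cohort(
        [
            ("a", 25.0, 6, "both", "diffuse_II", 8),
            ("b", 40.0, 3, None, "diffuse_III", 3),
            ("c", 63.0, 1, "none", "evacuated_mass", None),
            ("d", 55.0, 5, "both", "diffuse_I", 7),
        ]
    )


@pytest.fixture(scope="session")
def uppsala_config():
    return profile_config("uppsala", n=866, seed=20240)


@pytest.fixture(scope="session")
def uppsala_cohort(uppsala_config):
    return simulate_cohort(uppsala_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
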