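import numpy as np
import pandas as pd
import pytest

import bprx
from bprx.cohort import modeling_table, split_by_patient


@pytest.fixture(scope="session")
def small_cohort():
    """A modest heterogeneous cohort shared by the slower integration tests."""
    cfg = bprx.GeneratorConfig(n_patients=250, seed=7)
    return bprx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_visits(small_cohort):
    return bprx.build_visit_table(small_cohort)


@pytest.fixture(scope="session")
def small_split(small_visits):
    return split_by_patient(small_visits, seed=11)


@pytest.fixture(scope="session")
def fitted_schema(small_split):
    train, _, _ = small_split
    return bprx.default_schema().fit(modeling_table(train))


@pytest.fixture(scope="session")
def drlr_split_result(small_cohort, small_split, fitted_schema):
    """One fitted DRLR+KNN split: models, pools, panels, recommendations."""
    train, val, test = small_split
    policy = bprx.PolicyConfig(mode="deterministic")
    return bprx.run_split(
        train, val, test, algorithm="DRLR", schema=fitted_schema, k=20,
        policy=policy, truth=small_cohort.truth, epsilon=0.01,
    )


def toy_measurements(rows):
    return pd.DataFrame(rows, columns=["patient_id", "day", "kind", "value"])


@pytest.fixture()
def toy_timeline():
    """The worked toy timeline: SBP 150@d10, 140@d50, 135@d130 for patient 0."""
    meas = toy_measurements(
        [
            (0, 10, "sbp", 150.0),
            (0, 50, "sbp", 140.0),
            (0, 130, "sbp", 135.0),
        ]
    )
    rx = pd.DataFrame(
        [(0, 10, 99, "Thiazide")],
        columns=["patient_id", "start_day", "end_day", "drug_class"],
    )
    demo = pd.DataFrame(
        [
            {
                "patient_id": 0, "age": 60.0, "sex": "F", "race": "Black",
                "smoker": 0, "diabetes": 0, "systolic_hf": 0,
                "athero_hd": 0, "pvd": 0, "htn_dx": 1,
            }
        ]
    )
    return meas, rx, demo
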