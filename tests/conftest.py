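import numpy as np
import pandas as pd
import pytest

from picuree.ann import MLPSpec
from picuree.anthropometry import load_growth_reference
from picuree.cohort import CohortSpec, cohort_to_frame, generate_cohort
from picuree.equations import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def growth_refs():
    return load_growth_reference()


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=1)


@pytest.fixture(scope="session")
def cohort_patients(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def cohort_frame(cohort_patients):
    return cohort_to_frame(cohort_patients)


@pytest.fixture(scope="session")
def small_cohort_frame():
    return cohort_to_frame(generate_cohort(CohortSpec(seed=7, n=60)))


@pytest.fixture()
def fast_mlp():
    return MLPSpec(seed=0, max_epochs=150)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def complete_record():
    """One fully populated ventilated patient record."""
    return {
        "id": 0,
        "male": 1,
        "female": 0,
        "caucasian": 1,
        "asian": 0,
        "south_american": 0,
        "african": 0,
        "mechanically_ventilated": 1,
        "age": 4.0,
        "weight": 16.0,
        "height": 100.0,
        "bmi": 16.0,
        "z_bmi": 0.1,
        "z_hfa": -0.2,
        "z_wfa": 0.0,
        "z_wfh": 0.0,
        "normal_weight": 1,
        "overweight": 0,
        "obese": 0,
        "stunting": 0,
        "wasting_none": 1,
        "wasting_mild": 0,
        "wasting_moderate": 0,
        "wasting_severe": 0,
        "vo2": 0.09,
        "vco2": 0.07,
        "rq": 0.07 / 0.09,
        "heart_rate": 110.0,
        "sbp": 100.0,
        "dbp": 60.0,
        "body_temperature": 36.8,
        "sat_o2": 98.0,
        "hemoglobin": 10.0,
        "blood_glucose": 100.0,
        "crp": 2.0,
        "measured_ree": 622.2,
    }
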