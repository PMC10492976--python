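import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from produce_rx import default_population_spec, generate_cohort
from produce_rx.engine import SimulationParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def baseline_spec():
    return default_population_spec()


@pytest.fixture(scope="session")
def cohort_2k(baseline_spec):
    return generate_cohort(baseline_spec, 2000, seed=11)


@pytest.fixture(scope="session")
def cohort_500(baseline_spec):
    return generate_cohort(baseline_spec, 500, seed=5)


@pytest.fixture(scope="session")
def base_params():
    return SimulationParams.from_config()


def make_individual(**overrides):
    """A single valid baseline record as a dict."""
    rec = {
        "person_id": "p0000000",
        "survey_weight": 1.0,
        "age": 58.0,
        "sex": "female",
        "race_ethnicity": "NH-White",
        "education": "HS/GED",
        "income_poverty_ratio": "<1.30",
        "insurance": "medicare",
        "food_insecure": True,
        "diabetes": True,
        "hypertension": True,
        "cvd_history": False,
        "angina": False,
        "chd": False,
        "mi": False,
        "stroke": False,
        "bmi": 33.0,
        "hba1c": 7.5,
        "fruit_servings": 0.9,
        "veg_servings": 1.3,
    }
    rec.update(overrides)
    return rec


def make_cohort(records):
    """Cohort frame from a list of record dicts (column order preserved)."""
    from produce_rx.population import COHORT_COLUMNS

    return pd.DataFrame(records)[COHORT_COLUMNS]


@pytest.fixture
def tiny_cohort():
    return make_cohort(
        [
            make_individual(person_id="p0", survey_weight=1.0, age=40.0),
            make_individual(person_id="p1", survey_weight=3.0, age=60.0),
        ]
    )
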