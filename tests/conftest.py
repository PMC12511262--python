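import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from quizpk import (
    DosingRegimen,
    PKParameters,
    QUIZARTINIB_PARAMS,
    RandomEffectsModel,
    StudyDesign,
    generate_cohort,
)
from quizpk.cohort import GENERATOR_PARAMS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> PKParameters:
    return QUIZARTINIB_PARAMS


@pytest.fixture(scope="session")
def generator_params() -> PKParameters:
    return GENERATOR_PARAMS


@pytest.fixture(scope="session")
def onecmt_params() -> PKParameters:
    """Q3 = Q4 = 0 reduction: the engine collapses to the Bateman model."""
    return PKParameters(cl=1.0, v2=100.0, v3=1.0, v4=1.0, q3=0.0, q4=0.0, ka=1.68, f1=1.0)


@pytest.fixture(scope="session")
def regimen() -> DosingRegimen:
    return DosingRegimen(dose=30.0, interval=24.0)


@pytest.fixture(scope="session")
def re_model() -> RandomEffectsModel:
    return RandomEffectsModel()


@pytest.fixture(scope="session")
def cohort_53(re_model):
    """Default-design cohort with the study's missingness pattern (53 obs)."""
    return generate_cohort(
        StudyDesign(mimic_missingness=True), params=GENERATOR_PARAMS, seed=1
    )


@pytest.fixture(scope="session")
def cohort_full(re_model):
    """Default-design cohort with complete sampling (56 obs)."""
    return generate_cohort(StudyDesign(), params=GENERATOR_PARAMS, seed=1)


def make_frame(rows):
    """Build a dataset frame from (id, time, amt, evid, mdv, dv) tuples."""
    return pd.DataFrame(
        rows, columns=["ID", "TIME", "AMT", "EVID", "MDV", "DV"]
    ).astype({"ID": int, "EVID": int, "MDV": int})


@pytest.fixture(scope="session")
def tiny_frame():
    nan = np.nan
    return make_frame(
        [
            (1, 0.0, 30.0, 1, 1, nan),
            (1, 2.0, nan, 0, 0, 120.0),
            (1, 4.0, nan, 0, 0, 140.0),
            (2, 0.0, 30.0, 1, 1, nan),
            (2, 2.0, nan, 0, 0, 110.0),
        ]
    )
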