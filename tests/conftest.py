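import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from qsarmix import datasets
from qsarmix.composite import EndpointScoreTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def parent_scores() -> pd.DataFrame:
    return datasets.load_parent_scores()


@pytest.fixture(scope="session")
def parent_table(parent_scores) -> EndpointScoreTable:
    return EndpointScoreTable(
        parent_scores.set_index("abbrev")[["lds_1b06", "lds_6fpc"]]
    )


@pytest.fixture(scope="session")
def enr_derivatives() -> pd.DataFrame:
    return datasets.load_derivative_table("ENR")


@pytest.fixture(scope="session")
def spa_derivatives() -> pd.DataFrame:
    return datasets.load_derivative_table("SPA")


@pytest.fixture(scope="session")
def soil_scenarios() -> pd.DataFrame:
    return datasets.load_soil_scenarios()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
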