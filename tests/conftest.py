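import logging

import numpy as np
import pytest

from lungcea import AnalysisConfig, ModelSettings, SurvivalModel

# the duplicated-parameter-row notice is expected; keep test output clean
logging.getLogger("lungcea.parameters").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    cfg = AnalysisConfig()
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def settings() -> ModelSettings:
    return ModelSettings()


@pytest.fixture(scope="session")
def pdl1_atezo_pfs() -> SurvivalModel:
    return SurvivalModel("exponential", (0.01373,))


@pytest.fixture(scope="session")
def pdl1_atezo_os() -> SurvivalModel:
    return SurvivalModel("exponential", (0.00516,))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231024)
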