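import numpy as np
import pytest

from scmotor.config import GeneratorConfig
from scmotor.session_processing import process_session
from scmotor.synth import generate_session


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_control_trials=20, n_blink_trials=16, n_brem_trials=10, seed=42
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_processed(small_session):
    return process_session(small_session)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
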