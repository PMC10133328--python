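import warnings

import numpy as np
import pytest

from vallescape.synthetic import ScenarioConfig, generate_scenario

# the constant-vector normalization warning is expected in scenarios where a
# whole indicator is structurally flat; tests assert on it explicitly where
# it matters
warnings.filterwarnings("ignore", message="constant vector")


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture(scope="session")
def scenario(default_config):
    """One fully generated 31-unit synthetic study, shared across tests."""
    return generate_scenario(default_config, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
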