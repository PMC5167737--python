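import numpy as np
import pytest

from stngpe import InputSpec, ModelConfig, integrate_network


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig.default()


@pytest.fixture(scope="session")
def short_run(config):
    """A short autonomous simulation shared across tests (2 s, 0.5 s transient)."""
    return integrate_network(config, InputSpec(), duration=2000.0, transient=500.0,
                             seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
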