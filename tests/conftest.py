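import numpy as np
import pytest

from lighteyes.config import NetworkConfig
from lighteyes.model import LightEyesModel


@pytest.fixture(scope="session")
def default_model() -> LightEyesModel:
    """The default architecture (24 encoder convs, three-branch decoder),
    xavier-initialised with a fixed seed; shared read-only across tests."""
    model = LightEyesModel(NetworkConfig())
    model.init_weights(0)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
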