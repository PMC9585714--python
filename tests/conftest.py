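import numpy as np
import pytest

from sspkrecur import AcquisitionParams, AIFModel


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def aif() -> AIFModel:
    return AIFModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220908)
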