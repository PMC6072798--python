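import numpy as np
import pytest

from woodychange import BiomassModel, ChangeDefinition, SpeckleModel


@pytest.fixture(scope="session")
def bm() -> BiomassModel:
    return BiomassModel.published()


@pytest.fixture(scope="session")
def sm() -> SpeckleModel:
    return SpeckleModel.published()


@pytest.fixture(scope="session")
def defn() -> ChangeDefinition:
    return ChangeDefinition()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
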