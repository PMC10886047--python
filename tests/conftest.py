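import numpy as np
import pytest

from vigan.phantoms import PhantomSpec, make_phantom
from vigan.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.random((8, 8, 8)))


@pytest.fixture
def volume_pair(rng):
    v = Volume(rng.random((8, 8, 8)))
    vhat = Volume(np.clip(v.data + rng.normal(0, 0.1, v.shape), 0, 1))
    return v, vhat


@pytest.fixture(scope="session")
def vertebra16():
    return make_phantom(PhantomSpec(kind="vertebra", resolution=(16, 16, 16), seed=7))


def random_volume_of(rng, shape=(8, 8, 8)):
    return Volume(rng.random(shape))
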