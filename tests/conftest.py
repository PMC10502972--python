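import numpy as np
import pytest

from choroidseg import PhantomSpec, generate_phantom


@pytest.fixture
def tiny_spec():
    return PhantomSpec.tiny(seed=7)


@pytest.fixture
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_mask(rng, shape=(8, 8), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)
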