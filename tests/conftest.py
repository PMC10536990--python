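import numpy as np
import pytest

from mmstdyn import PhaseSpacePoint, build_model


@pytest.fixture(scope="session")
def models():
    """The three preset linear vibronic models at beta = 1."""
    return {i: build_model(i) for i in (1, 2, 3)}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_state(rng, scale=1.0):
    """A generic finite phase-space point for oracle comparisons."""
    return PhaseSpacePoint(x=scale * rng.normal(), p=scale * rng.normal(),
                           X=scale * rng.normal(size=2),
                           P=scale * rng.normal(size=2))


@pytest.fixture
def state(rng):
    return random_state(rng)
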