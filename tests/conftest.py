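import numpy as np
import pytest

from stalkpath import GridSpec, ParticleConfiguration


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec((20, 20, 20), (6.0, 6.0, 6.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def random_config(small_grid, rng) -> ParticleConfiguration:
    pos = rng.uniform(0.0, 6.0, size=(100, 3))
    return ParticleConfiguration(pos, small_grid.box_lengths)
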