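import numpy as np
import pytest
from hypothesis import settings

from junctionkit.synthetic_data import SceneParams, generate_fret_scene

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_scene():
    """A noise-free two-cell bleach scene at the wild-type fixture ratio."""
    params = SceneParams(fret_ratio_true=0.199, noise_sd=0.0, read_noise=0.0, seed=7)
    return generate_fret_scene(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
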