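import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_scene():
    """A small, easily separable synthetic scene (cached per test)."""
    from wheatear import easy_config, sample_scene
    return sample_scene(easy_config(256), seed=7)
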