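import numpy as np
import pytest

from ocra.model import ModelConfig, build_variant
from ocra.stimuli import gen_fixture_glyphs


@pytest.fixture(scope="session")
def glyph_source():
    return gen_fixture_glyphs(200, seed=0, split="train")


@pytest.fixture(scope="session")
def small_config():
    """Reduced model (fast to build/run) sharing the reference topology."""
    return ModelConfig(task="multimnist", feedback=False, recurrent_size=64,
                       n_primary=8, primary_dim=4, class_dim=8, timesteps=2)


@pytest.fixture(scope="session")
def small_model(small_config):
    return build_variant(small_config, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
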