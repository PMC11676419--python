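import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature model config for fast structural tests."""
    from strokeseg.model import ModelConfig

    return ModelConfig(stem_width=6, dilated_channels=8, growth=4,
                       dense_layers=2, embed_dim=16, ffn_dim=24, heads=2,
                       dropout=0.0)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    from strokeseg.model import build_model

    return build_model(tiny_config, seed=7)
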