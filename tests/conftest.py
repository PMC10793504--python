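import numpy as np
import pytest

from mcswin.config import ModelConfig
from mcswin.model import build_model
from mcswin.phantom import PhantomConfig, generate_phantom


def tiny_config(num_classes: int = 3, **overrides) -> ModelConfig:
    """Smallest config with the full topology: C=4, dims (4, 8, 16)."""
    kw = dict(
        in_channels=2,
        filters_per_channel=2,
        heads_per_stage=(1, 2, 4),
        mlp_ratio=1.0,
        num_classes=num_classes,
    )
    kw.update(overrides)
    return ModelConfig(**kw)


@pytest.fixture(scope="session")
def tiny_model():
    return build_model(tiny_config(), seed=0)


@pytest.fixture(scope="session")
def phantom_atlas():
    """Default 480×480×8 phantom with one region per visibility class."""
    return generate_phantom(PhantomConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
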