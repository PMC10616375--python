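import numpy as np
import pytest

from henuclei.model import ModelConfig, build_model, train
from henuclei.synthetic import SyntheticImageSpec, generate_scene

#: spec of the small patches used for desk-scale training experiments
TINY_PATCH = dict(
    height=64,
    width=64,
    n_nuclei=8,
    major_axis_range=(14.0, 22.0),
    minor_axis_range=(9.0, 14.0),
)


def tiny_scene(seed: int, **overrides):
    kwargs = {**TINY_PATCH, **overrides}
    return generate_scene(SyntheticImageSpec(seed=seed, **kwargs))


@pytest.fixture(scope="session")
def default_scene():
    """One default-parameter scene (256 px, 100 nuclei, moderate overlap)."""
    return generate_scene(SyntheticImageSpec(seed=11))


@pytest.fixture(scope="session")
def tiny_scenes():
    """Eight 64-px training patches."""
    return [tiny_scene(100 + i) for i in range(8)]


@pytest.fixture(scope="session")
def briefly_trained_model(tiny_scenes):
    """A small model trained for a handful of epochs — enough for contract
    tests (shapes, determinism, serialization), not for segmentation quality."""
    cfg = ModelConfig(channels=8, epochs=5, seed=0)
    model = build_model(cfg)
    model, _ = train(model, tiny_scenes[:2], cfg)
    return model
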