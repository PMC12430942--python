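import numpy as np
import pytest

from dgtta.core import Volume
from dgtta.pretrain import FeaturePipeline, SegmentationModel, TrainConfig, pretrain
from dgtta.synthetic import PhantomSpec, generate_phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.normal(size=(8, 8, 8)), (1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast phantom configuration for unit tests."""
    return PhantomSpec(grid_size=(32, 32, 32), structure_scale=0.5)


@pytest.fixture(scope="session")
def tiny_phantoms(tiny_spec):
    return generate_phantoms(tiny_spec, 4, seed=7)


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return TrainConfig(patch_size=(16, 16, 16), batch_size=1, epochs=3,
                       iters_per_epoch=8, seed=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_phantoms, tiny_train_cfg):
    """A briefly trained raw-intensity model shared across tests."""
    train_set = [(src, lm) for lm, src, _ in tiny_phantoms[:2]]
    model, log = pretrain(train_set, FeaturePipeline("none"), tiny_train_cfg)
    return model, log


@pytest.fixture
def untrained_model(rng):
    """A randomly initialized single-channel model (float64, 3 classes)."""
    from dgtta.network import UNet3D
    net = UNet3D(1, 3, base_channels=4, dtype=np.float64,
                 rng=np.random.default_rng(5))
    return SegmentationModel(net, FeaturePipeline("none"), [0, 1, 2])
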