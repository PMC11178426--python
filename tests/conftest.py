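import numpy as np
import pytest

from tumnet import TrainConfig, build_tumnet, train
from tumnet.phantom import generate_dataset


@pytest.fixture(scope="session")
def phantom_training_run():
    """One full training run on separable phantoms, shared across tests.

    200 fused MRI/CT phantom pairs (half tumorous), 20 epochs, fixed
    seed; the model, its samples, and the config are reused by the
    classification-recovery and pipeline tests to avoid retraining.
    """
    samples = generate_dataset(200, tumor_fraction=0.5, rng_seed=7)
    images = [s.fused("average") for s in samples]
    labels = [s.label for s in samples]
    cfg = TrainConfig(epochs=20, rng_seed=7)
    model = train(build_tumnet(num_classes=2), images, labels, cfg)
    return model, samples, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_pair(rng):
    from tumnet import GrayImage

    a = GrayImage(rng.integers(0, 256, (32, 32)).astype(float))
    b = GrayImage(rng.integers(0, 256, (32, 32)).astype(float))
    return a, b
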