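import numpy as np
import pytest

from rarefynet.model import RarefyNetConfig, build_model
from rarefynet.raster_io import GridTransform, NDVIMap, PatchTensor, SamplePair
from rarefynet.synthetic import SceneConfig
from rarefynet.training import TrainConfig, train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_arch():
    """Down-scaled architecture for fast training tests."""
    return RarefyNetConfig(maps_block1=4, maps_block2=6, dense_width=8,
                           dropout_p=0.1)


@pytest.fixture
def tiny_scene_config():
    """A 4x4-cell vineyard scene that generates in well under a second."""
    return SceneConfig(width_m=40.0, height_m=40.0, gsd=0.05, cell_size=10.0,
                       seed=0)


def random_ndvi_map(rng, shape=(8, 8), mask=None):
    values = rng.uniform(-0.2, 0.9, shape)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return NDVIMap(values, mask, GridTransform(0.0, 0.0, 10.0))


def identity_pairs(rng, n):
    """Samples whose reference equals the raw centre pixel (identity task).

    A third of the samples zero out an edge or corner of the ring, mimicking
    the zero-padded patches that boundary pixels of a real raster produce.
    """
    pairs = []
    for i in range(n):
        patch = rng.uniform(0.0, 1.0, (3, 3))
        locations = rng.uniform(0.0, 1.0, (3, 3))
        style = i % 3
        if style == 1:      # edge pixel: one padded side
            side = rng.integers(4)
            sl = [np.s_[0, :], np.s_[2, :], np.s_[:, 0], np.s_[:, 2]][side]
            patch[sl] = 0.0
            locations[sl] = 0.0
        elif style == 2:    # corner pixel: two padded sides
            patch[0, :] = patch[:, 0] = 0.0
            locations[0, :] = locations[:, 0] = 0.0
        pairs.append(SamplePair(PatchTensor(patch, locations, i), float(patch[1, 1])))
    return pairs


@pytest.fixture(scope="session")
def identity_model():
    """A small network trained on the identity task (y = raw centre pixel).

    Shared across tests that need a trained model whose behaviour is known:
    it should reproduce its input almost exactly thanks to the residual path.
    """
    rng = np.random.default_rng(7)
    pairs = identity_pairs(rng, 300)
    train_pairs, test_pairs = pairs[:240], pairs[240:]
    cfg = TrainConfig(epochs=300, augmentation_rotations=7, seed=7)
    arch = RarefyNetConfig(maps_block1=4, maps_block2=6, dense_width=8,
                           dropout_p=0.1)
    model = build_model(arch, seed=7)
    model, history = train(model, train_pairs, test_pairs, cfg)
    return model, history, test_pairs
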