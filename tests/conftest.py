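import numpy as np
import pytest

import synapsedetect as sd


@pytest.fixture(scope="session")
def small_scene():
    """A small synthetic scene shared by fast tests."""
    cfg = sd.SceneConfig(
        shape=(64, 128, 128),
        n_synapses=5,
        n_mitochondria=3,
        n_myelin=1,
        membrane_density=12,
        min_synapse_separation_vox=35,
        seed=1,
    )
    return sd.generate_scene(cfg)


@pytest.fixture(scope="session")
def small_scene_model(small_scene):
    """Feature stack, labels and trained model for the small scene."""
    labels = sd.make_training_labels(small_scene, strokes_per_class=8, seed=1)
    stack = sd.compute_feature_stack(small_scene.volume)
    model = sd.train(stack, labels, sd.ForestConfig(seed=0))
    return stack, labels, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def coord_volume(shape, fn):
    """Volume whose value at (z, y, x) is fn(z, y, x) — analytic test inputs."""
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    return sd.Volume3D(fn(zz, yy, xx))


def interior(shape, margin):
    """Slices selecting voxels at least ``margin`` from every face."""
    return tuple(slice(int(np.ceil(margin)), s - int(np.ceil(margin))) for s in shape)
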