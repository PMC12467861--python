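import numpy as np
import pytest

from gaitintent import default_config, generate_dataset
from gaitintent.pipeline import dataset_features


@pytest.fixture(scope="session")
def sim_config():
    return default_config()


@pytest.fixture(scope="session")
def small_dataset(sim_config):
    """Two trials per mode — enough to cover all 13 classes cheaply."""
    return generate_dataset(sim_config, trials_per_mode=2, seed=11)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    fm, trial_ids = dataset_features(small_dataset)
    return fm, trial_ids


@pytest.fixture(scope="session")
def toy_clusters():
    """Three well-separated Gaussian blobs (perfectly separable)."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    X = np.vstack([c + 0.3 * rng.standard_normal((30, 2)) for c in centers])
    y = np.repeat(["a", "b", "c"], 30)
    return X, y
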