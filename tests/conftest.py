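import numpy as np
import pytest

import treefates as tf


@pytest.fixture(scope="session")
def small_dataset():
    """Default two-fork simulation at reduced size, shared across tests."""
    cfg = tf.default_config(seed=7, n_cells_per_segment=60, n_noise_genes=60)
    return tf.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def y_points():
    """Noiseless Y-shaped skeleton: 300 points on three arms."""
    rng = np.random.default_rng(0)
    t = rng.uniform(0, 1, 100)
    arm1 = np.column_stack([t, np.zeros(100)])  # stem to origin
    t2 = rng.uniform(0, 1, 100)
    arm2 = np.column_stack([-t2 * 0.7, t2 * 0.7])
    t3 = rng.uniform(0, 1, 100)
    arm3 = np.column_stack([-t3 * 0.7, -t3 * 0.7])
    return np.vstack([arm1, arm2, arm3])
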