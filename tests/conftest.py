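import numpy as np
import pytest

import meshbench as mb


@pytest.fixture(scope="session")
def folded_mesh():
    """642-vertex toy cortex with 5 mm folds (the benchmark's working size)."""
    return mb.gen_mesh(642, fold_amplitude=5.0, fold_frequency=6, radius=70.0, seed=1)


@pytest.fixture(scope="session")
def small_mesh():
    """162-vertex mesh for cheap forward/inverse toys."""
    return mb.gen_mesh(162, fold_amplitude=3.0, fold_frequency=4, radius=70.0, seed=2)


@pytest.fixture(scope="session")
def sensors64():
    return mb.gen_sensor_array(64, seed=0)


@pytest.fixture(scope="session")
def sensors16():
    return mb.gen_sensor_array(16, seed=0)


@pytest.fixture(scope="session")
def small_gain(small_mesh, sensors16):
    return mb.gain_matrix(small_mesh, sensors16)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
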