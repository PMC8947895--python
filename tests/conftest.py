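import numpy as np
import pytest

from dpkhsi import HyperCube, SceneSpec, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cube(rng):
    """A 3x4x5 integer cube with deterministic content."""
    return HyperCube(np.arange(3 * 4 * 5, dtype=np.int32).reshape(3, 4, 5))


@pytest.fixture(scope="session")
def scene3():
    """A small 3-class labelled scene shared by preprocessing/CNN tests."""
    spec = SceneSpec(rows=24, cols=24, n_classes=3, n_bands=16, snr_db=30.0, seed=2)
    cube, labels, endmembers = make_scene(spec)
    return cube, labels, endmembers, spec
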