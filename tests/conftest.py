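import numpy as np
import pytest

from paniclepheno.cloud3d import BoundingCube
from paniclepheno.io import PointCloud
from paniclepheno.synthetic import SyntheticPanicleSpec, make_scene


@pytest.fixture(scope="session")
def scene():
    """One default chamber scene with truth, shared across tests."""
    return make_scene(SyntheticPanicleSpec(rng_seed=3))


@pytest.fixture(scope="session")
def small_cube():
    return BoundingCube(resolution=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n, span=100.0):
    """Random colored cloud for round-trip / binning tests."""
    points = rng.uniform(-span, span, (n, 3))
    colors = rng.integers(0, 256, (n, 3))
    return PointCloud(points, colors)
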