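import numpy as np
import pytest

from darktensor import full_geometry, orthogonal_subset


@pytest.fixture(scope="session")
def full_geom():
    return full_geometry()


@pytest.fixture(scope="session")
def ortho_geom():
    return orthogonal_subset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_orthonormal_pair(rng):
    """A random (n_hat, e_hat) pose pair, uniform over orientations."""
    from darktensor.tensors import random_rotation

    R = random_rotation(rng)
    return R[:, 2], R[:, 0]
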