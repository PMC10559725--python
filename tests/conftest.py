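import numpy as np
import pytest

from fwpenumbra.config import CohortConfig
from fwpenumbra.phantom import simulate_subject
from fwpenumbra.scheme import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured cohort configuration."""
    return CohortConfig(grid_shape=(36, 36, 36), voxel_size=(2.5, 2.5, 2.5),
                        n_subjects=2, seed=7)


@pytest.fixture(scope="session")
def small_subject(small_config):
    return simulate_subject(small_config, 0)


def axisym_tensor6(md, fa, direction=(1.0, 0.0, 0.0)):
    """Axially symmetric tensor with given MD/FA, as 6-vector."""
    e = np.asarray(direction, float)
    e = e / np.linalg.norm(e)
    root = np.sqrt(3.0 - 2.0 * fa ** 2)
    lam1 = md * (1.0 + 2.0 * fa / root)
    lam23 = md * (1.0 - fa / root)
    D = lam23 * np.eye(3) + (lam1 - lam23) * np.outer(e, e)
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
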