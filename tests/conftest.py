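import numpy as np
import pytest

from ivimdti import Config1Spec, make_scheme, mean_diffusivity
from ivimdti.scheme import AcquisitionScheme


@pytest.fixture(scope="session")
def scheme():
    """The full 11-shell / 12-b0 / 60-direction protocol (612 measurements)."""
    return make_scheme(seed=0)


@pytest.fixture(scope="session")
def small_scheme():
    """Reduced 3-shell scheme for fast solver exercises."""
    return make_scheme(b_values=(0.0, 250.0, 650.0, 1150.0), n_b0=2,
                       n_directions=8, seed=1)


@pytest.fixture(scope="session")
def config1():
    return Config1Spec(seed=0)


@pytest.fixture(scope="session")
def config1_truth(config1, scheme):
    return config1.ground_truth(scheme)


@pytest.fixture(scope="session")
def truth_mds(config1_truth):
    return (
        mean_diffusivity(config1_truth.d_star),
        mean_diffusivity(config1_truth.d),
    )


def make_single_direction_scheme(g, bvals):
    g = np.asarray(g, float)
    g = g / np.linalg.norm(g)
    bvals = np.asarray(bvals, float)
    bvecs = np.tile(g, (bvals.size, 1))
    bvecs[bvals == 0] = 0.0
    return AcquisitionScheme(bvals, bvecs)
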