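import numpy as np
import pytest

from cryofit.synthetic import make_toy_protein, simulate_map
from cryofit.maps import DensityMap, build_mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy20():
    """20-residue self-avoiding toy protein with chain topology."""
    return make_toy_protein(20, seed=1)


@pytest.fixture(scope="session")
def toy12():
    return make_toy_protein(12, seed=3)


@pytest.fixture(scope="session")
def noisefree_map(toy20):
    """Noise-free simulated map of the toy protein at 10 Å resolution."""
    return build_mask(simulate_map(toy20, 10.0, 3.0), 1e-9)


@pytest.fixture
def small_obs(rng):
    """A tiny random observed map (50 voxels) for likelihood algebra."""
    values = rng.normal(1.0, 0.5, size=(5, 5, 2))
    return DensityMap(values, origin=[0.0, 0.0, 0.0], spacing=1.5)
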