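import numpy as np
import pytest

from geoloci import LandscapeSim, simulate_ibd
from geoloci.io import doses_to_features


@pytest.fixture(scope="session")
def ibd_fixture():
    """Default steep-cline landscape: 300 samples, 300 loci, 4:1 hotspots."""
    G, C, truth = simulate_ibd(LandscapeSim(seed=1))
    return G, C, truth


@pytest.fixture(scope="session")
def ibd_features(ibd_fixture):
    G, C, _ = ibd_fixture
    return doses_to_features(G), C


@pytest.fixture(scope="session")
def small_fixture():
    """Small, fast landscape for I/O and pipeline tests."""
    G, C, truth = simulate_ibd(
        LandscapeSim(seed=7, n_samples=80, n_loci=60, missing_rate=0.05)
    )
    return G, C, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
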