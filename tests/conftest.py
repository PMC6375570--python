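import numpy as np
import pytest

from teloherit import SimParams, simulate_population
from teloherit.trf import SizeLadder, calibrate_ladder


@pytest.fixture(scope="session")
def default_params():
    return SimParams(seed=0)


@pytest.fixture(scope="session")
def default_table(default_params):
    """One simulated breeding table at the study's default conditions."""
    return simulate_population(default_params)


@pytest.fixture(scope="session")
def big_table():
    """A large colony (~9000 offspring) for low-noise empirical checks."""
    return simulate_population(SimParams(n_pairs_start=300, seed=11))


@pytest.fixture(scope="session")
def ladder():
    # bands roughly like a 1 kb ladder over the telomere smear range
    sizes = np.array([48500, 24000, 15000, 10000, 8000, 6000, 5000,
                      4000, 3000, 2000, 1500, 1000], dtype=float)
    dist = 10.0 + 40.0 * (np.log10(48500) - np.log10(sizes)) / (
        np.log10(48500) - np.log10(1000))
    return SizeLadder(sizes, dist)


@pytest.fixture(scope="session")
def calib(ladder):
    return calibrate_ladder(ladder)
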