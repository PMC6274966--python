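import pytest

from gramlattice.condensation import cluster_geometry
from gramlattice.synthetic_data import SimConfig, simulate_radial_profile


@pytest.fixture(scope="session")
def profile():
    """Calibrated synthetic radial distribution (A12 = 520.1 A^2)."""
    return simulate_radial_profile(SimConfig(seed=0))


@pytest.fixture(scope="session")
def geom12(profile):
    """M = 12 rigid-cluster geometry on the calibrated profile."""
    return cluster_geometry(12, profile)
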