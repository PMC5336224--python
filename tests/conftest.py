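import numpy as np
import pytest

from firenet.catalogue import IgnitionParams, generate_ignition_catalogue
from firenet.communities import generate_communities
from firenet.grid import LandscapeGrid, generate_landscape
from firenet.weather import generate_weather


def make_uniform_grid(n=101, cell_size=30.0, rate=15.0, intensity=1000.0,
                      label="NF-M"):
    """Single-tenure landscape with constant spread rate (oracle substrate)."""
    shape = (n, n)
    return LandscapeGrid(
        n_rows=n, n_cols=n, cell_size=cell_size, origin=(0.0, 0.0),
        tenure_id=np.zeros(shape, dtype=np.int16),
        fuel_class=np.zeros(shape, dtype=np.int16),
        base_rate=np.full(shape, rate, dtype=float),
        intensity_coeff=np.full(shape, intensity, dtype=float),
        tenure_labels={0: label},
    )


@pytest.fixture(scope="session")
def uniform_grid():
    return make_uniform_grid()


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(60, 60, 100.0, 3, 600, seed=5)


@pytest.fixture(scope="session")
def communities(landscape):
    return generate_communities(landscape, 3, 2000, seed=11)


@pytest.fixture(scope="session")
def weather():
    return generate_weather(18, seed=6)


@pytest.fixture(scope="session")
def catalogue(landscape, communities, weather):
    return generate_ignition_catalogue(
        landscape, communities, weather, IgnitionParams(), seed=7
    )
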