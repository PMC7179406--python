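import numpy as np
import pytest

from aquaphonon import band_structure, table1_device, water_cell


@pytest.fixture(scope="session")
def cell():
    """Homogeneous liquid-water unit cell from the tabulated band edges."""
    return water_cell()


@pytest.fixture(scope="session")
def bands(cell):
    return band_structure(cell)


@pytest.fixture(scope="session")
def device():
    """Homogeneous N = 1 water device with identical reservoirs."""
    return table1_device()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cells(rng, n, mass_range=(1e-27, 1e-25), spring_range=(0.1, 2e3)):
    """Log-uniform random unit cells (labels fixed so K1 >= K2)."""
    from aquaphonon import UnitCell

    lo_m, hi_m = np.log(mass_range)
    lo_k, hi_k = np.log(spring_range)
    cells = []
    for _ in range(n):
        m1, m2 = np.exp(rng.uniform(lo_m, hi_m, 2))
        k1, k2 = np.sort(np.exp(rng.uniform(lo_k, hi_k, 2)))[::-1]
        cells.append(UnitCell(M1=m1, M2=m2, K1=k1, K2=k2, l=3e-10))
    return cells
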