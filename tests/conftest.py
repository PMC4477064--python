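import numpy as np
import pytest

from surfhomog import build_icosphere, build_neighbor_table


@pytest.fixture(scope="session")
def mesh2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def mesh3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def table2_ring1(mesh2):
    return build_neighbor_table(mesh2, ring_order=1)


@pytest.fixture(scope="session")
def table3_ring1(mesh3):
    return build_neighbor_table(mesh3, ring_order=1)


@pytest.fixture(scope="session")
def table3_ring2(mesh3):
    return build_neighbor_table(mesh3, ring_order=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
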