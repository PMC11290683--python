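import numpy as np
import pytest

from slowwave.connectome import ConnectivityConfig, build_connectome
from slowwave.mesh import assign_hierarchy, assign_parcels, build_icosphere


@pytest.fixture(scope="session")
def ico1_mesh():
    mesh = build_icosphere(1)
    mesh = assign_parcels(mesh, 6, seed=0)
    return assign_hierarchy(mesh)


@pytest.fixture(scope="session")
def ico2_mesh():
    mesh = build_icosphere(2)
    mesh = assign_parcels(mesh, 12, seed=0)
    return assign_hierarchy(mesh)


@pytest.fixture(scope="session")
def ico1_network(ico1_mesh):
    cfg = ConnectivityConfig(thalamus_level=1)
    conn = build_connectome(ico1_mesh, cfg, seed=1, thalamus=True)
    return ico1_mesh, conn


@pytest.fixture(scope="session")
def ico2_network(ico2_mesh):
    cfg = ConnectivityConfig(thalamus_level=None)
    conn = build_connectome(ico2_mesh, cfg, seed=1, thalamus=False)
    return ico2_mesh, conn


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
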