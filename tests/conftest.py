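import numpy as np
import pytest
from hypothesis import settings

import plasmovib as pv

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ico55():
    return pv.build_mackay_icosahedron(2)


@pytest.fixture(scope="session")
def ico13():
    return pv.build_mackay_icosahedron(1)


@pytest.fixture(scope="session")
def disk3nm():
    return pv.build_graphene_disk(3.0)


@pytest.fixture(scope="session")
def gold_params():
    return pv.materials.gold()


@pytest.fixture(scope="session")
def drude_params():
    return pv.materials.drude_gold()


@pytest.fixture(scope="session")
def graphene_params():
    return pv.materials.graphene(0.4)


@pytest.fixture
def random_cluster():
    """Well-separated random 20-atom geometry with a neighbor graph."""
    rng = np.random.default_rng(42)
    pos = rng.uniform(0, 12.0, (20, 3))
    # push overlapping atoms apart deterministically
    for _ in range(200):
        d = pos[:, None] - pos[None, :]
        r = np.linalg.norm(d, axis=-1) + np.eye(20) * 1e9
        i, j = np.unravel_index(np.argmin(r), r.shape)
        if r[i, j] > 2.6:
            break
        pos[i] += 0.5 * d[i, j] / r[i, j]
    s = pv.NanoStructure(pos, np.array(["Au"] * 20))
    return pv.neighbor_graph(s, 4.5)


@pytest.fixture(scope="session")
def small_molecule():
    return pv.make_fixture(3, n_atoms=8)
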