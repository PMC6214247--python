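import numpy as np
import pytest

from painmark import Connectome, SyntheticConfig, generate_study


def make_connectome(edges, n, binary=True, regions=None, weights=None):
    """Small-graph helper: build a Connectome from an edge list."""
    a = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        a[i, j] = a[j, i] = w
    ids = [f"n{k}" for k in range(n)]
    region_of = {v: (regions[k] if regions else "S1") for k, v in enumerate(ids)}
    return Connectome(a, ids, region_of, binary=binary)


@pytest.fixture
def k3():
    return make_connectome([(0, 1), (1, 2), (0, 2)], 3)


@pytest.fixture
def path3():
    return make_connectome([(0, 1), (1, 2)], 3)


@pytest.fixture
def path4():
    return make_connectome([(0, 1), (1, 2), (2, 3)], 4)


@pytest.fixture
def star4():
    """Star with 3 leaves (center node 0)."""
    return make_connectome([(0, 1), (0, 2), (0, 3)], 4)


@pytest.fixture
def k4():
    return make_connectome([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], 4)


@pytest.fixture
def f6():
    """K4 on nodes 0-3 plus node 4 adjacent to 0, 1, 2 (worked LCP example)."""
    return make_connectome(
        [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (0, 4), (1, 4), (2, 4)], 5
    )


@pytest.fixture
def two_triangles():
    return make_connectome([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study: full 8-step schedule, small ensembles."""
    cfg = SyntheticConfig(n_matrices_per_step=30, keep_middle=12, seed=11)
    series, truth = generate_study(cfg)
    return series, truth, cfg


@pytest.fixture(scope="session")
def default_study():
    """One default-scale synthetic study (8 x 1000 -> 400 x 31 nodes)."""
    cfg = SyntheticConfig(seed=5)
    series, truth = generate_study(cfg)
    return series, truth, cfg
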