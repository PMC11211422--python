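import numpy as np
import pytest

from nitriver.domain import (NOT_LAND, OUTLET, FlowNetwork, GridDomain,
                             RegionMap, build_synthetic_domain)


def make_chain_domain(n: int, cell_area: float = 1.0e12,
                      lake_fraction: float = 0.0):
    """1 x n domain with a simple chain 0 -> 1 -> ... -> OUTLET."""
    domain = GridDomain(
        n_lat=1, n_lon=n,
        cell_area=np.full(n, cell_area),
        land_mask=np.ones(n, dtype=bool),
        lake_fraction=np.full(n, lake_fraction),
        has_reach=np.ones(n, dtype=bool))
    downstream = np.arange(1, n + 1, dtype=np.int64)
    downstream[-1] = OUTLET
    net = FlowNetwork(downstream)
    region_id = np.ones(n, dtype=np.int64)
    return domain, net, RegionMap(region_id=region_id)


@pytest.fixture(scope="session")
def small_domain():
    return build_synthetic_domain(6, 6, land_fraction=0.8, seed=1)


@pytest.fixture(scope="session")
def tiny_domain():
    return build_synthetic_domain(3, 3, land_fraction=1.0, seed=2)
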