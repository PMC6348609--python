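import numpy as np
import pytest

import hgtclock as hc


def random_topology(rng: np.random.Generator, n_leaves: int) -> hc.Topology:
    """Random bifurcating topology built by sequential pair-joining."""
    newicks = [f"L{i}" for i in range(n_leaves)]
    while len(newicks) > 1:
        i, j = sorted(rng.choice(len(newicks), size=2, replace=False))
        b = newicks.pop(j)
        a = newicks.pop(i)
        newicks.append(f"({a},{b})")
    return hc.parse_newick(newicks[0] + ";")


def random_chronogram(rng: np.random.Generator, n_leaves: int,
                      root_age: float = 100.0) -> hc.Chronogram:
    """Random chronogram: random topology, ages by recursive thinning."""
    topo = random_topology(rng, n_leaves)
    ages = np.zeros(topo.n_nodes)
    ages[topo.root] = root_age
    for node in reversed(range(topo.n_nodes - 1)):
        if topo.children[node]:
            ages[node] = ages[topo.parent[node]] * rng.uniform(0.3, 0.95)
    return hc.Chronogram(topology=topo, ages=ages)


@pytest.fixture(scope="session")
def hgt_fixture():
    """The default synthetic HGT dataset (donor+recipient, 20 tips)."""
    return hc.make_hgt_fixture(hc.FixtureSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
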