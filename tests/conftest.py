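import networkx as nx
import numpy as np
import pytest

from netprio import FixtureSpec, Network, SeedSet, generate_hetero_fixture


@pytest.fixture
def edge_net():
    return Network.from_edges([("a", "b")])


@pytest.fixture
def triangle():
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star4():
    return Network.from_edges([("hub", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def path3():
    return Network.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def two_cliques():
    """Two 20-node cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in (0, 20):
        for a in range(20):
            for b in range(a + 1, 20):
                g.add_edge(f"n{base + a:02d}", f"n{base + b:02d}")
    g.add_edge("n00", "n20")
    return Network.from_networkx(g)


@pytest.fixture(scope="session")
def hetero_fixture():
    spec = FixtureSpec(n_genes=60, n_diseases=5, modules=((15, 0.6),),
                       n_module_seeds=5, rng_seed=11)
    return generate_hetero_fixture(spec)


def random_connected_net(rng: np.random.Generator, n: int, p: float = 0.15) -> Network:
    """Erdos-Renyi graph patched to be connected (no dangling columns)."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    comps = list(nx.connected_components(g))
    for a, b in zip(comps, comps[1:]):
        g.add_edge(next(iter(a)), next(iter(b)))
    g = nx.relabel_nodes(g, {i: f"v{i:03d}" for i in g.nodes})
    return Network.from_networkx(g)
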