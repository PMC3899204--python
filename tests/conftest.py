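import networkx as nx
import pytest

from graphin import InteractionNetwork, build_catalogs


@pytest.fixture(scope="session")
def catalogs():
    return build_catalogs()


@pytest.fixture(scope="session")
def gcat(catalogs):
    return catalogs[0]


@pytest.fixture(scope="session")
def icat(catalogs):
    return catalogs[1]


@pytest.fixture()
def triangle():
    return InteractionNetwork([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture()
def path3():
    return InteractionNetwork([("A", "B"), ("B", "C")])


@pytest.fixture()
def star4():
    """Center c with three leaves."""
    return InteractionNetwork([("c", "l1"), ("c", "l2"), ("c", "l3")])


def random_networks(n_graphs, *, max_n=12, seed=0, ps=(0.2, 0.5)):
    """Seeded Erdős–Rényi instances for equivalence sweeps."""
    rng = nx.utils.create_random_state(seed)
    out = []
    for t in range(n_graphs):
        n = int(rng.randint(4, max_n + 1))
        p = ps[t % len(ps)]
        g = nx.gnp_random_graph(n, p, seed=int(rng.randint(0, 2**31 - 1)))
        out.append(InteractionNetwork.from_networkx(g))
    return out
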