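import networkx as nx
import pytest


def str_graph(g: nx.Graph) -> nx.Graph:
    """Relabel any networkx graph to string node ids (package convention)."""
    return nx.relabel_nodes(nx.Graph(g), {n: str(n) for n in g.nodes()})


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return str_graph(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def figure1():
    from nlcomm import figure1_fixture

    return figure1_fixture()


@pytest.fixture
def two_triangles():
    """Two disjoint triangles: {0,1,2} and {3,4,5}."""
    return str_graph(nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3)))


@pytest.fixture
def bridged_triangles():
    """Triangles {a,b,c} and {d,e,f} joined by the bridge edge c-d."""
    g = nx.Graph()
    for tri in (("a", "b", "c"), ("d", "e", "f")):
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(tri[i], tri[j])
    g.add_edge("c", "d")
    return g
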