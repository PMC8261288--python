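"""Per-node and per-pair primitives used in seed selection.

The influence score F(u) combines three local signals: the degree D(u), the
local clustering coefficient C(u) of u's neighborhood, and the Jaccard
similarity between u and each neighbor,

    F(u) = sum over v in N(u) of
           D(u) (1 + C(u)) * D(v) (1 + C(v)) / (1 - sim(u, v))^2 .

A node sitting in a dense, well-knit neighborhood (high C, high sim to its
neighbors) accumulates a large F and is a good community seed.  The older
gravity-style influence (no clustering-coefficient boost) is kept as
``influence_ces`` for comparison: F(u) with C forced to 0 equals the
gravity influence with unit damping coefficient.

All neighborhoods are open: N(u) never contains u itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "SIM_CAP",
    "NodeScoreTable",
    "jaccard_similarity",
    "local_clustering",
    "influence_nlc",
    "influence_ces",
    "compute_scores",
]

# Twin nodes (identical open neighborhoods) have sim = 1, which would put a
# zero in the (1 - sim)^2 denominator; sim is capped just below 1 so that
# "more similar => larger influence" holds without infinities.
SIM_CAP = 1.0 - 1e-9


def _check_node(g: nx.Graph, u) -> None:
    if u not in g:
        raise KeyError(f"node {u!r} not in graph")


def jaccard_similarity(g: nx.Graph, u, v) -> float:
    """Jaccard similarity |N(u) ∩ N(v)| / |N(u) ∪ N(v)| of open neighborhoods.

    Returns 0 when the union is empty (two isolated nodes).
    """
    _check_node(g, u)
    _check_node(g, v)
    nu, nv = set(g[u]), set(g[v])
    union = len(nu | nv)
    if union == 0:
        return 0.0
    return len(nu & nv) / union


def local_clustering(g: nx.Graph, u) -> float:
    """Local clustering coefficient C(u) = 2 K(u) / (|N(u)| (|N(u)|-1)).

    K(u) counts edges among the neighbors of u; C(u) = 0 when u has at most
    one neighbor.
    """
    _check_node(g, u)
    return nx.clustering(g, u)


@dataclass
class NodeScoreTable:
    """Memoized per-node degree / clustering / influence scores.

    Pairwise similarities are computed lazily and cached; values agree with
    direct recomputation.
    """

    graph: nx.Graph
    degree: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    influence: dict = field(default_factory=dict)
    _sim_cache: dict = field(default_factory=dict, repr=False)

    def sim(self, u, v) -> float:
        key = (u, v) if str(u) <= str(v) else (v, u)
        val = self._sim_cache.get(key)
        if val is None:
            val = jaccard_similarity(self.graph, u, v)
            self._sim_cache[key] = val
        return val

    def to_tsv(self, path: str | Path) -> None:
        """Dump node, degree, C and F as a TSV (debugging aid)."""
        with open(path, "w") as fh:
            fh.write("node\tdegree\tclustering\tinfluence\n")
            for n in self.graph.nodes():
                fh.write(
                    f"{n}\t{self.degree[n]}\t{self.clustering[n]:.6g}"
                    f"\t{self.influence[n]:.6g}\n"
                )


def influence_nlc(g: nx.Graph, u, scores: NodeScoreTable) -> float:
    """Neighbor-local-clustering influence F(u).

    Nonnegative; zero exactly for isolated nodes.
    """
    _check_node(g, u)
    d_u = g.degree(u)
    c_u = scores.clustering[u]
    total = 0.0
    for v in g[u]:
        d_v = g.degree(v)
        c_v = scores.clustering[v]
        s = min(scores.sim(u, v), SIM_CAP)
        total += (d_u * (1.0 + c_u) * d_v * (1.0 + c_v)) / (1.0 - s) ** 2
    return total


def influence_ces(g: nx.Graph, v, gf: float) -> float:
    """Gravity-style influence gf * Σ_{u∈N(v)} D(v) D(u) / (1 - sim(v,u))².

    The ancestor of :func:`influence_nlc` without the clustering-coefficient
    boost; ``gf`` is the damping coefficient of the community magnetic
    interference theory.
    """
    if gf < 0:
        raise ValueError(f"gf must be nonnegative, got {gf}")
    _check_node(g, v)
    d_v = g.degree(v)
    total = 0.0
    for u in g[v]:
        s = min(jaccard_similarity(g, v, u), SIM_CAP)
        total += d_v * g.degree(u) / (1.0 - s) ** 2
    return gf * total


def compute_scores(g: nx.Graph) -> NodeScoreTable:
    """Populate degree, clustering coefficient and influence for all nodes."""
    scores = NodeScoreTable(graph=g)
    scores.degree = dict(g.degree())
    scores.clustering = nx.clustering(g)
    for u in g.nodes():
        scores.influence[u] = influence_nlc(g, u, scores)
    return scores
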