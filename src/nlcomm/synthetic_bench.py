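"""Planted-overlapping-community benchmark graphs and small fixtures.

The generator emulates the parameter surface of LFR-style benchmarks —
node count, target average degree, mixing fraction mu, number of
overlapping nodes and memberships per overlapping node — with a much
simpler planted-partition scheme: communities of (roughly) equal size,
Bernoulli edges with an inside-community probability calibrated so that a
fraction (1 − mu) of a node's expected degree is internal.  It does NOT
reproduce LFR's power-law degree and community-size machinery; see the
README.  That trade keeps ground truth exact and generation deterministic
per seed, which is what a test harness needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "PlantedConfig",
    "PlantedTruth",
    "generate_planted",
    "figure1_fixture",
    "two_clique_bridge",
]

logger = logging.getLogger(__name__)


@dataclass
class PlantedConfig:
    """Parameters of a planted-overlapping-community graph.

    n: node count.  k_avg: target mean degree.  mu: mixing fraction in
    [0, 1) — the expected share of a node's edges that leave its own
    communities.  on: number of overlapping nodes; each holds ``om``
    memberships (all other nodes hold exactly one).  n_comm: number of
    planted communities.  Deterministic per ``seed``.
    """

    n: int
    k_avg: float
    mu: float
    on: int
    om: int
    n_comm: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k_avg >= self.n:
            raise ValueError(f"k_avg={self.k_avg} infeasible for n={self.n}")
        if self.k_avg <= 0:
            raise ValueError("k_avg must be positive")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must be in [0, 1)")
        if self.on > self.n:
            raise ValueError("on cannot exceed n")
        if self.on > 0 and self.om < 2:
            raise ValueError("om must be >= 2 for overlapping nodes")
        if self.n_comm < 2:
            raise ValueError("n_comm must be >= 2")
        if self.on > 0 and self.om > self.n_comm:
            raise ValueError("om cannot exceed n_comm")


@dataclass
class PlantedTruth:
    """A generated graph together with its planted ground-truth cover."""

    graph: nx.Graph
    cover: list
    config: PlantedConfig | None = None


def generate_planted(cfg: PlantedConfig) -> PlantedTruth:
    """Generate a planted-partition graph with overlapping nodes.

    Nodes are split into ``n_comm`` nearly equal base communities; the
    first ``on`` nodes (one per community, round-robin, so overlaps spread
    out) additionally join ``om − 1`` further communities.  Each unordered
    node pair gets an edge with probability ``p_in`` when the two nodes
    share a community and ``p_out`` otherwise, calibrated so the expected
    degree is ``k_avg`` with an expected outside share of ``mu``.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes = [str(i) for i in range(cfg.n)]

    base = [i % cfg.n_comm for i in range(cfg.n)]  # round-robin balance
    memberships: list[set[int]] = [{b} for b in base]
    # overlap nodes: every n_comm-th node so each community donates fairly
    stride = max(cfg.n // max(cfg.on, 1), 1)
    overlap_ids = [min(i * stride, cfg.n - 1) for i in range(cfg.on)]
    overlap_ids = sorted(set(overlap_ids))[: cfg.on]
    # fall back to first free ids if the stride produced collisions
    i = 0
    while len(overlap_ids) < cfg.on:
        if i not in overlap_ids:
            overlap_ids.append(i)
        i += 1
    for idx in overlap_ids:
        extra = [c for c in range(cfg.n_comm) if c not in memberships[idx]]
        rng.shuffle(extra)
        memberships[idx] |= set(extra[: cfg.om - 1])

    comm_size = cfg.n / cfg.n_comm
    same_partners = max(comm_size - 1.0, 1.0)
    other_partners = max(cfg.n - comm_size, 1.0)
    p_in = (1.0 - cfg.mu) * cfg.k_avg / same_partners
    p_out = cfg.mu * cfg.k_avg / other_partners
    if p_in > 1.0:
        logger.warning("p_in=%.3f clipped to 1; realized degree will fall short", p_in)
        p_in = 1.0
    p_out = min(p_out, 1.0)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(cfg.n):
        mi = memberships[i]
        for j in range(i + 1, cfg.n):
            p = p_in if mi & memberships[j] else p_out
            if p > 0.0 and rng.random() < p:
                g.add_edge(nodes[i], nodes[j])

    cover = [set() for _ in range(cfg.n_comm)]
    for i, ms in enumerate(memberships):
        for c in ms:
            cover[c].add(nodes[i])
    return PlantedTruth(graph=g, cover=cover, config=cfg)


def figure1_fixture() -> nx.Graph:
    """Worked-example neighborhood: node 12 and its six neighbors.

    Node "12" is adjacent to {"8", "11", "13", "14", "15", "16"}; among
    those neighbors exactly the edges (8,13) and (11,16) exist.  Encodes
    only these facts — enough to reproduce the clustering coefficient
    C(12) = 2·2 / (6·5) = 2/15.
    """
    g = nx.Graph()
    for v in ("8", "11", "13", "14", "15", "16"):
        g.add_edge("12", v)
    g.add_edge("8", "13")
    g.add_edge("11", "16")
    return g


def two_clique_bridge(k: int) -> PlantedTruth:
    """Two k-cliques joined by one bridge edge; canonical overlap test-bed.

    Nodes "a0".."a{k-1}" and "b0".."b{k-1}" form the cliques; the bridge is
    ("a0", "b0").  Ground truth: each clique plus the opposite bridge
    endpoint, so both bridge endpoints are overlapping nodes.
    """
    if k < 3:
        raise ValueError(f"clique size must be >= 3, got {k}")
    g = nx.Graph()
    a = [f"a{i}" for i in range(k)]
    b = [f"b{i}" for i in range(k)]
    for grp in (a, b):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(grp[i], grp[j])
    g.add_edge(a[0], b[0])
    cover = [set(a) | {b[0]}, set(b) | {a[0]}]
    return PlantedTruth(graph=g, cover=cover)
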