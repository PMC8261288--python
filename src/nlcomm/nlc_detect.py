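"""Overlapping community detection via neighbor-local-clustering seeding.

Pipeline
--------
1.  **Central node selection.**  Nodes whose influence F beats every
    neighbor's become candidates; candidates are accepted greedily in
    descending (working) F, subject to a similarity cap ``alpha`` against
    already-accepted seeds; on acceptance the working F of the new seed's
    neighbors is damped (community magnetic interference) so adjacent nodes
    do not both seed communities.
2.  **Central edge sets.**  Each seed claims its incident edges whose
    endpoint similarity exceeds the seed's mean neighbor similarity — the
    nucleus of one community.
3.  **Non-central edge clustering.**  Every remaining edge joins the central
    edge set with the smallest average distance, where the distance between
    two edges is the product of a Jaccard distance on edge neighborhoods and
    a shortest-path link distance — finite for any two edges in the same
    connected component, which is what lets distant edges be placed at all.
4.  **Edge → node conversion.**  A node belongs to every community one of
    its assigned edges belongs to; multi-membership nodes are overlapping.
5.  **Overlap pruning.**  An overlapping node keeps a membership only where
    it is sufficiently wired to the community's non-overlapping core.

The whole pipeline is deterministic for a fixed graph and parameter set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .graph_core import canonical_edge, node_sort_key
from .node_metrics import NodeScoreTable, compute_scores

logger = logging.getLogger(__name__)

__all__ = [
    "NLCParams",
    "CentralEdgeSets",
    "select_central_nodes",
    "build_central_edge_sets",
    "edge_link_distance",
    "edge_jaccard_distance",
    "edge_distance",
    "assign_noncentral_edges",
    "edges_to_node_cover",
    "prune_overlaps",
    "run_nlc",
]

UNASSIGNED = None  # EdgeCover value for edges no central edge set can reach


@dataclass
class NLCParams:
    """Tunables of the detection pipeline.

    alpha
        Similarity cap between accepted seeds, in [0, 1].  Two candidate
        seeds more similar than ``alpha`` would nucleate near-duplicate
        communities, so the later one is rejected.
    prune
        Overlap pruning threshold, in [0, 1]; larger values prune harder.
    gf
        Community-magnetic-interference coefficient; ``None`` means use the
        graph's edge/node ratio |E|/|V|.  Neighbors of an accepted seed have
        their working influence multiplied by ``min(gf, 1/gf)`` so the
        revision always reduces their candidacy.
    min_prune_size
        Communities smaller than this are never pruned.
    max_prune_iters
        Cap on pruning passes (normally a fixed point is reached far
        earlier).
    seed
        Recorded for provenance; the algorithm itself is deterministic.
    """

    alpha: float = 0.1
    prune: float = 0.3
    gf: float | None = None
    min_prune_size: int = 3
    max_prune_iters: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.prune <= 1.0:
            raise ValueError(f"prune must be in [0, 1], got {self.prune}")
        if self.gf is not None and self.gf <= 0:
            raise ValueError(f"gf must be positive, got {self.gf}")
        if self.max_prune_iters < 1:
            raise ValueError("max_prune_iters must be positive")

    def resolve_gf(self, g: nx.Graph) -> float:
        if self.gf is not None:
            return self.gf
        n = g.number_of_nodes()
        return g.number_of_edges() / n if n else 1.0


@dataclass
class CentralEdgeSets:
    """Ordered seed communities: a central node plus its central edges.

    The list position is the community index.  Every edge appears in at most
    one set (first claim wins).
    """

    centers: list = field(default_factory=list)
    edge_sets: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.centers)

    def all_edges(self) -> set:
        out: set = set()
        for es in self.edge_sets:
            out |= es
        return out


def select_central_nodes(
    g: nx.Graph, scores: NodeScoreTable, params: NLCParams
) -> list:
    """Pick seed nodes by local influence maxima with similarity exclusion.

    Candidacy is evaluated against the *working* influence, which starts at
    F and is revised as seeds are accepted: a node is a candidate when its
    working F beats every neighbor's (ties broken in its favor iff it
    precedes the neighbor in canonical node order).  Repeatedly, the
    strongest candidate is accepted unless it is more similar than
    ``alpha`` to an already-accepted seed (then it is rejected for good);
    on acceptance the seed's neighbors' working F is multiplied by the
    community magnetic interference factor, which both demotes them and can
    promote nodes they previously dominated.  Deterministic.
    """
    if g.number_of_nodes() == 0:
        return []
    gf = params.resolve_gf(g)
    damp = min(gf, 1.0 / gf) if gf > 0 else 1.0
    logger.debug("CMI damping factor applied to seed neighbors: %g", damp)

    working = dict(scores.influence)
    done: set = set()  # accepted or rejected — out of the running
    accepted: list = []
    while True:
        best = None
        best_key = None
        for u in g.nodes():
            if u in done or g.degree(u) == 0:
                continue
            wu, ku = working[u], node_sort_key(u)
            beaten = False
            for v in g[u]:
                if working[v] > wu or (working[v] == wu and node_sort_key(v) < ku):
                    beaten = True
                    break
            if beaten:
                continue
            key = (wu, _neg_key(u))
            if best is None or key > best_key:
                best, best_key = u, key
        if best is None:
            break
        done.add(best)
        if all(scores.sim(best, c) <= params.alpha for c in accepted):
            accepted.append(best)
            for v in g[best]:
                working[v] *= damp
    return accepted


class _neg_key:
    """Inverts node_sort_key so max() prefers the earlier node id on ties."""

    __slots__ = ("key",)

    def __init__(self, node) -> None:
        self.key = node_sort_key(node)

    def __lt__(self, other: "_neg_key") -> bool:
        return self.key > other.key

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_key) and self.key == other.key


def build_central_edge_sets(
    g: nx.Graph, cn: list, scores: NodeScoreTable
) -> CentralEdgeSets:
    """Turn each seed into a central edge set.

    A seed claims its incident edges with endpoint similarity strictly above
    its mean neighbor similarity; if that rule selects nothing (e.g. all
    similarities equal), the maximum-similarity edges are taken instead.
    Edges already claimed by an earlier seed are skipped; a seed left with
    no claimable edges is dropped with a warning.
    """
    ces = CentralEdgeSets()
    claimed: set = set()
    for u in cn:
        neighbors = list(g[u])
        if not neighbors:
            logger.warning("central node %r has degree 0; skipped", u)
            continue
        sims = {v: scores.sim(u, v) for v in neighbors}
        ave = sum(sims.values()) / len(neighbors)
        eligible = [
            v for v in neighbors if canonical_edge(u, v) not in claimed
        ]
        if not eligible:
            logger.warning(
                "all edges of central node %r already claimed; skipped", u
            )
            continue
        chosen = [v for v in eligible if sims[v] > ave]
        if not chosen:
            best = max(sims[v] for v in eligible)
            chosen = [v for v in eligible if sims[v] == best]
        edge_set = {canonical_edge(u, v) for v in chosen}
        claimed |= edge_set
        ces.centers.append(u)
        ces.edge_sets.append(edge_set)
    return ces


def edge_link_distance(g: nx.Graph, e1, e2) -> float:
    """Topological distance between two edges.

    0 for identical edges; otherwise 1 + the shortest path length between
    the closest pair of endpoints (adjacent edges are at distance 1);
    ``inf`` when the edges lie in different components.
    """
    e1, e2 = canonical_edge(*e1), canonical_edge(*e2)
    if e1 == e2:
        return 0.0
    best = math.inf
    for x in e1:
        lengths = nx.single_source_shortest_path_length(g, x)
        for y in e2:
            d = lengths.get(y)
            if d is not None and d < best:
                best = d
    return 1.0 + best if best < math.inf else math.inf


def edge_jaccard_distance(g: nx.Graph, e1, e2) -> float:
    """Jaccard distance between the closed neighborhoods of two edges.

    The base set of an edge is its two endpoints plus all their neighbors;
    structurally twin edges therefore get distance 0.
    """
    s1 = _edge_neighborhood(g, e1)
    s2 = _edge_neighborhood(g, e2)
    union = len(s1 | s2)
    if union == 0:
        return 0.0
    return 1.0 - len(s1 & s2) / union


def _edge_neighborhood(g: nx.Graph, e) -> set:
    u, v = e
    return {u, v} | set(g[u]) | set(g[v])


def edge_distance(g: nx.Graph, e1, e2) -> float:
    """Combined distance Dis = Jaccard distance × link distance.

    0 for identical edges; ``inf`` exactly when the edges are disconnected
    and their neighborhoods differ.
    """
    link = edge_link_distance(g, e1, e2)
    if link == 0.0:
        return 0.0
    jac = edge_jaccard_distance(g, e1, e2)
    if math.isinf(link):
        return math.inf if jac > 0.0 else 0.0
    return jac * link


def assign_noncentral_edges(g: nx.Graph, ces: CentralEdgeSets) -> dict:
    """Cluster every non-central edge to its nearest central edge set.

    The distance from edge e to set CE_i is the mean of Dis(e, c) over the
    central edges c in CE_i; e is assigned to the argmin (ties to the lowest
    community index).  Edges at infinite distance from every set stay
    unassigned.  Central edges keep their own set's index.
    """
    cover: dict = {}
    for i, es in enumerate(ces.edge_sets):
        for e in es:
            cover[e] = i

    # BFS once from every distinct endpoint of a central edge; an edge's link
    # distance to a central edge is then a constant-time lookup.
    dist_from: dict = {}
    central_endpoints = {x for es in ces.edge_sets for e in es for x in e}
    for x in central_endpoints:
        dist_from[x] = nx.single_source_shortest_path_length(g, x)

    nbhd_cache: dict = {}

    def nbhd(e):
        s = nbhd_cache.get(e)
        if s is None:
            s = _edge_neighborhood(g, e)
            nbhd_cache[e] = s
        return s

    for u, v in g.edges():
        e = canonical_edge(u, v)
        if e in cover:
            continue
        best_idx = UNASSIGNED
        best_dls = math.inf
        se = nbhd(e)
        for i, es in enumerate(ces.edge_sets):
            total = 0.0
            for c in es:
                d_link = min(
                    (
                        dist_from[x][y]
                        for x in c
                        for y in e
                        if y in dist_from[x]
                    ),
                    default=math.inf,
                )
                if math.isinf(d_link):
                    total = math.inf
                    break
                sc = nbhd(c)
                union = len(se | sc)
                jac = 1.0 - len(se & sc) / union if union else 0.0
                total += jac * (1.0 + d_link)
            dls = total / len(es)
            if dls < best_dls:
                best_dls = dls
                best_idx = i
        if best_idx is not UNASSIGNED and math.isfinite(best_dls):
            cover[e] = best_idx
        else:
            cover[e] = UNASSIGNED
    return cover


def edges_to_node_cover(g: nx.Graph, ec: dict) -> list:
    """Convert an edge assignment into an overlapping node cover.

    Node n joins community i iff some assigned edge incident to n carries
    index i; nodes touched by edges of several communities overlap.
    """
    n_comm = max((i for i in ec.values() if i is not UNASSIGNED), default=-1) + 1
    cover: list = [set() for _ in range(n_comm)]
    for (u, v), i in ec.items():
        if i is UNASSIGNED:
            continue
        cover[i].add(u)
        cover[i].add(v)
    return [c for c in cover if c]


def prune_overlaps(g: nx.Graph, cover: list, params: NLCParams) -> list:
    """Trim memberships of excessively overlapping nodes.

    For each overlapping node n and each of its communities j, the ratio of
    n's edges into the non-overlapping core of j to its edges into all its
    communities' cores is compared with ``prune``; memberships below the
    threshold are dropped.  Safeguards: communities smaller than
    ``min_prune_size`` are never pruned; when every ratio is below the
    threshold the node keeps (only) its best-ratio community; a node whose
    cores are all unreachable (zero denominator) keeps all memberships; no
    node ends with zero memberships.  Iterates to a fixed point (capped).
    """
    cover = [set(c) for c in cover]
    for iteration in range(params.max_prune_iters):
        membership: dict = {}
        for j, comm in enumerate(cover):
            for n in comm:
                membership.setdefault(n, set()).add(j)
        overlapping = sorted(
            (n for n, ms in membership.items() if len(ms) >= 2), key=node_sort_key
        )
        if not overlapping:
            break
        non_overlap = [
            {n for n in comm if len(membership[n]) == 1} for comm in cover
        ]
        sizes = [len(c) for c in cover]
        changed = False
        for n in overlapping:
            clus = sorted(membership[n])
            con = {
                j: sum(1 for nb in g[n] if nb in non_overlap[j]) for j in clus
            }
            denom = sum(con.values())
            if denom == 0:
                continue
            ratios = {j: con[j] / denom for j in clus}
            if all(r < params.prune for r in ratios.values()):
                best = max(clus, key=lambda j: (ratios[j], -j))
                drop = [j for j in clus if j != best]
            else:
                drop = [j for j in clus if ratios[j] < params.prune]
            for j in drop:
                if sizes[j] < params.min_prune_size:
                    continue  # small communities are never pruned
                if len(membership[n]) <= 1:
                    break  # node must keep at least one membership
                cover[j].discard(n)
                membership[n].discard(j)
                sizes[j] -= 1
                changed = True
        if not changed:
            break
    else:
        logger.warning("pruning stopped at iteration cap %d", params.max_prune_iters)
    return [c for c in cover if c]


def run_nlc(g: nx.Graph, params: NLCParams | None = None) -> list:
    """Run the full detection pipeline and return an overlapping cover.

    The cover is a list of node sets; a node may appear in several sets and
    nodes in seedless components may appear in none.
    """
    if params is None:
        params = NLCParams()
    if g.number_of_edges() == 0:
        logger.warning("graph has no edges; returning empty cover")
        return []
    scores = compute_scores(g)
    cn = select_central_nodes(g, scores, params)
    if not cn:
        logger.warning("no central nodes found; returning empty cover")
        return []
    ces = build_central_edge_sets(g, cn, scores)
    ec = assign_noncentral_edges(g, ces)
    cover = edges_to_node_cover(g, ec)
    return prune_overlaps(g, cover, params)
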