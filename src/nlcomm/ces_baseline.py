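"""Distance formulas of the central-edge-selection (CES) baseline.

Only the two formulas needed for the comparison demo are provided: the
edge-edge similarity ELC and the edge-to-central-edge-set distance DNC.
The full CES pipeline (its seeding, clustering and pruning) is out of
scope.

ELC is a neighborhood-overlap similarity, so it is exactly 0 for edge
pairs whose endpoint neighborhoods are disjoint — i.e. for edges more than
two hops apart.  DNC inherits that blind spot: an edge at topological
distance >= 3 from every central edge is at DNC 0 from *every* community
and cannot be placed, which is the deficiency the combined
Jaccard-times-link distance of :mod:`nlcomm.nlc_detect` repairs.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["elc", "dnc"]


def elc(g: nx.Graph, e1, e2) -> float:
    """Edge-edge similarity: pooled neighborhood overlap of the endpoints.

    For e1=(a,b), e2=(c,d) the four endpoint pairings (a,c), (a,d), (b,c),
    (b,d) contribute their neighborhood intersections and unions, and ELC is
    the ratio of summed intersection sizes to summed union sizes (0 when all
    unions are empty).  Symmetric; in [0, 1].
    """
    a, b = e1
    c, d = e2
    for x in (a, b, c, d):
        if x not in g:
            raise KeyError(f"node {x!r} not in graph")
    inter = 0
    union = 0
    for x in (a, b):
        nx_ = set(g[x])
        for y in (c, d):
            ny = set(g[y])
            inter += len(nx_ & ny)
            union += len(nx_ | ny)
    if union == 0:
        return 0.0
    return inter / union


def dnc(g: nx.Graph, e, ce) -> float:
    """Distance from edge ``e`` to a central edge set ``ce``.

    DNC(e, CE) = Σ_j ELC(e, e_j) (S - ELC(e, e_j)) / S with S = Σ_m
    ELC(e, e_m); returns 0 when S = 0 (edge invisible to the whole set) —
    the degenerate case the combined distance of the main pipeline avoids.
    """
    ce = list(ce)
    if not ce:
        raise ValueError("central edge set must be nonempty")
    sims = [elc(g, e, ej) for ej in ce]
    s = sum(sims)
    if s == 0.0:
        return 0.0
    return sum(x * (s - x) for x in sims) / s
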