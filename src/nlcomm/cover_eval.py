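"""Quality metrics for overlapping community covers.

A *cover* is a list of node sets; nodes may belong to several communities
and some nodes may be uncovered.  Provided metrics:

EQ
    extended (overlapping) modularity — each node's contribution is split
    across its O_v memberships:
    EQ = (1/2|E|) Σ_i Σ_{v,w ∈ C_i} (A_vw − D_v D_w / 2|E|) / (O_v O_w),
    over ordered pairs including v = w (A_vv = 0).  At most 1; larger is
    better.
NMI
    overlapping normalized mutual information in the
    Lancichinetti-Fortunato-Kertész (LFK) form,
    NMI = 1 − [H(R|P) + H(P|R)] / 2, with normalized conditional entropies
    built from per-community binary membership variables; 1 for identical
    covers.
CR
    coverage rate — percentage of the node universe assigned to at least
    one community.
NNC
    normalized community-count agreement max(1 − |NSC − NPC| / NSC, 0).
OR
    overlapping rate — fraction of covered nodes with >= 2 memberships.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "EvalReport",
    "eq_modularity",
    "onmi",
    "coverage_rate",
    "nnc",
    "overlap_rate",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """One row of metrics for a cover (nmi/nnc need ground truth)."""

    eq: float
    cr: float
    or_rate: float
    npc: int
    nmi: float | None = None
    nnc: float | None = None

    def to_tsv(self, header: bool = True) -> str:
        cols = ["eq", "nmi", "cr", "nnc", "or", "npc"]
        vals = [
            f"{self.eq:.4f}",
            "" if self.nmi is None else f"{self.nmi:.4f}",
            f"{self.cr:.1f}",
            "" if self.nnc is None else f"{self.nnc:.4f}",
            f"{self.or_rate:.4f}",
            str(self.npc),
        ]
        if self.nmi is None:
            cols = [c for c, v in zip(cols, vals) if v != ""]
            vals = [v for v in vals if v != ""]
        lines = []
        if header:
            lines.append("\t".join(cols) + "  # NMI variant: LFK")
        lines.append("\t".join(vals))
        return "\n".join(lines)


def _membership_counts(cover: list) -> dict:
    counts: dict = {}
    for comm in cover:
        for v in comm:
            counts[v] = counts.get(v, 0) + 1
    return counts


def eq_modularity(g: nx.Graph, cover: list) -> float:
    """Extended modularity of an overlapping cover.

    Uncovered nodes contribute nothing; a node in O_v communities has each
    of its pair contributions divided by O_v.  The whole graph as a single
    community scores exactly 0.
    """
    if not cover:
        return 0.0
    for comm in cover:
        for v in comm:
            if v not in g:
                raise ValueError(f"cover node {v!r} not in graph")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    two_m = 2.0 * m
    o = _membership_counts(cover)
    deg = dict(g.degree())
    total = 0.0
    for comm in cover:
        members = list(comm)
        for v in members:
            dv = deg[v]
            ov = o[v]
            adj = g[v]
            for w in members:
                a_vw = 1.0 if w in adj else 0.0  # A_vv = 0 (no self-loops)
                total += (a_vw - dv * deg[w] / two_m) / (ov * o[w])
    return total / two_m


def _h(p: float) -> float:
    """Entropy contribution −p·log2 p, 0 at p = 0."""
    return 0.0 if p <= 0.0 else -p * math.log2(p)


def _cond_entropy_norm(xs: list, ys: list, n: int) -> float:
    """Mean normalized conditional entropy H(X|Y) over communities of X.

    Each community is a binary membership variable over an n-node universe.
    For a pair (X_k, Y_l) the conditional entropy comes from the 2x2 joint
    counts, admissible only when h(P11)+h(P00) >= h(P01)+h(P10) (otherwise
    Y_l conveys spurious "anti-membership" information and H(X_k) is used
    instead).  H(X_k|Y) is the minimum over l, normalized by H(X_k);
    communities with H(X_k)=0 contribute 0.
    """
    total = 0.0
    for xk in xs:
        hx = _h(len(xk) / n) + _h(1 - len(xk) / n)
        if hx == 0.0:
            continue
        best = hx  # fall back to H(X_k) if nothing admissible beats it
        for yl in ys:
            p11 = len(xk & yl) / n
            p10 = len(xk - yl) / n
            p01 = len(yl - xk) / n
            p00 = 1.0 - p11 - p10 - p01
            if _h(p11) + _h(p00) < _h(p01) + _h(p10):
                continue
            hy = _h(len(yl) / n) + _h(1 - len(yl) / n)
            joint = _h(p11) + _h(p10) + _h(p01) + _h(p00)
            best = min(best, joint - hy)
        total += best / hx
    return total / len(xs)


def onmi(truth: list, pred: list, universe: set) -> float:
    """LFK overlapping NMI between two covers over a common node universe.

    Symmetric, in [0, 1], and exactly 1 for identical covers.
    """
    if not truth or not pred:
        logger.warning("onmi: empty cover; returning 0")
        return 0.0
    n = len(universe)
    if n == 0:
        raise ValueError("universe must be nonempty")
    xs = [set(c) for c in truth]
    ys = [set(c) for c in pred]
    h_xy = _cond_entropy_norm(xs, ys, n)
    h_yx = _cond_entropy_norm(ys, xs, n)
    return 1.0 - (h_xy + h_yx) / 2.0


def coverage_rate(cover: list, universe: set) -> float:
    """Percentage of the universe covered by at least one community."""
    if not universe:
        raise ValueError("universe must be nonempty")
    covered = set()
    for comm in cover:
        covered |= set(comm)
    return 100.0 * len(covered & set(universe)) / len(universe)


def nnc(nsc: int, npc: int) -> float:
    """Agreement between true (nsc) and predicted (npc) community counts."""
    if nsc < 1:
        raise ValueError(f"nsc must be >= 1, got {nsc}")
    return max(1.0 - abs(nsc - npc) / nsc, 0.0)


def overlap_rate(cover: list) -> float:
    """Fraction of covered nodes belonging to two or more communities."""
    counts = _membership_counts(cover)
    if not counts:
        return 0.0
    return sum(1 for c in counts.values() if c >= 2) / len(counts)


def evaluate(
    g: nx.Graph,
    pred: list,
    truth: list | None = None,
    universe: set | None = None,
) -> EvalReport:
    """Compute the full metric row for a predicted cover.

    ``universe`` defaults to the graph's node set; nmi and nnc are filled
    only when a ground-truth cover is supplied.
    """
    if universe is None:
        universe = set(g.nodes())
    report = EvalReport(
        eq=eq_modularity(g, pred),
        cr=coverage_rate(pred, universe),
        or_rate=overlap_rate(pred),
        npc=len(pred),
    )
    if truth is not None:
        report.nmi = onmi(truth, pred, universe)
        report.nnc = nnc(len(truth), len(pred))
    return report
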