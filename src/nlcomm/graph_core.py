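"""Graph model, edge-list / interaction-table I/O and PPI preprocessing.

Graphs are plain :class:`networkx.Graph` objects with **string** node
identifiers.  Protein identifiers ("Q62447") and numeric-looking labels
("12") must coexist, so numeric-looking ids are never coerced to integers.

File dialects
-------------
edge list
    one edge per line, two whitespace-separated node ids, ``#`` comments.
DIP-style table
    tab-separated, two configurable interactor columns (defaults 0 and 1).
community file
    one community per line, space-separated node ids.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "canonical_edge",
    "node_sort_key",
    "read_edge_list",
    "write_edge_list",
    "read_dip_table",
    "preprocess_ppi",
    "read_community_file",
    "write_community_file",
]


class EdgeListParseError(ValueError):
    """Raised when an input line cannot be parsed as an edge."""


def node_sort_key(node: str) -> tuple[int, str]:
    """Total order on string node ids.

    Sorting by ``(len, str)`` orders decimal labels numerically ("2" < "10")
    while remaining a total, deterministic order for arbitrary identifiers.
    """
    s = str(node)
    return (len(s), s)


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the unordered edge ``{u, v}`` as a canonically ordered tuple."""
    if node_sort_key(u) <= node_sort_key(v):
        return (u, v)
    return (v, u)


def read_edge_list(path: str | Path, comment_prefix: str = "#") -> nx.Graph:
    """Read an undirected simple graph from a whitespace-delimited edge list.

    Duplicate edges are collapsed, self-loops are dropped and node ids are
    kept as strings.  An empty file yields an empty graph.

    Raises
    ------
    EdgeListParseError
        If a non-comment line has fewer than two tokens (the message names
        the offending line number).
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment_prefix):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected at least 2 tokens, "
                    f"got {len(tokens)}"
                )
            if len(tokens) > 2:
                logger.warning(
                    "%s: line %d has %d columns; extra columns ignored "
                    "(graphs are unweighted)", path, lineno, len(tokens)
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                g.add_node(u)
                continue
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write ``g`` as a canonical, sorted edge list (isolated nodes last)."""
    edges = sorted(
        (canonical_edge(u, v) for u, v in g.edges()),
        key=lambda e: (node_sort_key(e[0]), node_sort_key(e[1])),
    )
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u} {v}\n")
        for n in sorted(nx.isolates(g), key=node_sort_key):
            fh.write(f"# isolated {n}\n")


def read_dip_table(
    path: str | Path,
    col_a: int = 0,
    col_b: int = 1,
    id_pattern: str | None = None,
) -> nx.Graph:
    """Read a DIP-style tab-delimited interaction table as a graph.

    The first row is treated as a header and skipped iff either indicated
    cell fails ``id_pattern`` (a regular expression; the default accepts any
    non-empty token, i.e. no header is assumed).  Self-interactions are
    dropped and duplicate interactions collapsed.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    ncols = df.shape[1]
    if col_a >= ncols or col_b >= ncols:
        raise EdgeListParseError(
            f"{path}: requested columns ({col_a}, {col_b}) but table has "
            f"{ncols} column(s)"
        )
    if ncols > 2:
        logger.warning(
            "%s: table has %d columns; only columns %d and %d are used",
            path, ncols, col_a, col_b,
        )
    pairs = df.iloc[:, [col_a, col_b]].astype(str)
    if id_pattern is not None and len(pairs) > 0:
        import re

        pat = re.compile(id_pattern)
        first = pairs.iloc[0]
        if not (pat.fullmatch(first.iloc[0]) and pat.fullmatch(first.iloc[1])):
            pairs = pairs.iloc[1:]
    g = nx.Graph()
    for a, b in pairs.itertuples(index=False):
        if pd.isna(a) or pd.isna(b):
            continue
        a, b = str(a), str(b)
        if a == b:
            g.add_node(a)
            continue
        g.add_edge(a, b)
    return g


def preprocess_ppi(g: nx.Graph, min_component_size: int = 3) -> nx.Graph:
    """Clean a raw interaction network the way PPI studies usually do.

    Removes self-loops and deletes every connected component with fewer than
    ``min_component_size`` nodes.  Idempotent; node and edge counts are
    non-increasing.
    """
    if min_component_size < 1:
        raise ValueError(f"min_component_size must be >= 1, got {min_component_size}")
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from((u, v) for u, v in g.edges() if u != v)
    keep: set[str] = set()
    for comp in nx.connected_components(out):
        if len(comp) >= min_component_size:
            keep |= comp
    return out.subgraph(keep).copy()


def read_community_file(path: str | Path) -> list[set[str]]:
    """Read a cover: one community per line, space-separated node ids."""
    cover: list[set[str]] = []
    with open(path) as fh:
        for line in fh:
            members = set(line.split())
            if members:
                cover.append(members)
    return cover


def write_community_file(cover: Iterable[Sequence[str] | set[str]], path: str | Path) -> None:
    """Write a cover in the community-file dialect (sorted for determinism)."""
    with open(path, "w") as fh:
        for comm in cover:
            fh.write(" ".join(sorted(comm, key=node_sort_key)) + "\n")
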