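"""Plain-text readers and writers for interaction networks.

Two formats are supported: a two-column whitespace edge list (the format
used for the background interactome) and SIF ("A pp B"), the simple
interaction format understood by most network tools.  Networks are plain
``networkx.Graph`` objects: undirected, simple, string-labeled.
"""

from __future__ import annotations

import warnings

import networkx as nx

__all__ = ["read_edge_list", "write_edge_list", "write_sif"]


def read_edge_list(path) -> nx.Graph:
    """Read a two-column edge list; '#' lines are comments.

    Symmetric duplicates collapse to one undirected edge; self-loops are
    dropped with a warning.  Lines with a single token become isolated
    nodes, which lets round-trips preserve degree-zero nodes.
    """
    g = nx.Graph()
    loops = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 1:
                g.add_node(parts[0])
                continue
            if len(parts) != 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            u, v = parts
            if u == v:
                loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
    if loops:
        warnings.warn(f"dropped {loops} self-loop(s) while reading {path}")
    return g


def write_edge_list(net: nx.Graph, path) -> None:
    """Write sorted edges (and then isolated nodes) one per line."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")
        for v in sorted(v for v in net if net.degree(v) == 0):
            fh.write(f"{v}\n")


def write_sif(net: nx.Graph, path, relation: str = "pp") -> None:
    """Write the network in SIF; isolated nodes appear as bare labels."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for v in sorted(v for v in net if net.degree(v) == 0):
            fh.write(f"{v}\n")
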