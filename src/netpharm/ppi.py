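"""Seed expansion against a background interactome and network merging.

Each seed gene list (formula targets on one side, disease-related genes
on the other) is expanded to its one-hop neighborhood in the background
protein-protein interactome — the induced subgraph on the seeds present
in the interactome plus all of their direct neighbors.  The two expanded
networks are then merged with intersection semantics: the merged node
set is the intersection of the two node sets, and the merged edge set is
every edge of either input with both endpoints retained.  The merge is
therefore no larger than either input, which is what makes a subsequent
hub screen on the shared neighborhood meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["expand_seeds", "merge_networks", "network_summary", "NetworkSummary"]


def expand_seeds(
    seeds: set[str], interactome: nx.Graph, depth: int = 1
) -> nx.Graph:
    """Induced subgraph on the seeds plus their depth-hop neighborhood.

    Seeds absent from the interactome are dropped with a warning; an
    empty effective seed set yields an empty network (with a warning).
    """
    if depth < 1:
        raise ValueError("expansion depth must be >= 1")
    seeds = set(seeds)
    effective = seeds & set(interactome)
    missing = seeds - effective
    if missing:
        warnings.warn(
            f"{len(missing)} seed(s) absent from the interactome "
            f"(e.g. {sorted(missing)[:3]})"
        )
    if not effective:
        warnings.warn("no seeds present in the interactome; empty network")
        return nx.Graph()
    frontier = set(effective)
    keep = set(effective)
    for _ in range(depth):
        frontier = {w for v in frontier for w in interactome[v]} - keep
        keep |= frontier
    return interactome.subgraph(keep).copy()


def merge_networks(net_a: nx.Graph, net_b: nx.Graph) -> nx.Graph:
    """Intersection merge: shared nodes, union of edges within them."""
    common = set(net_a) & set(net_b)
    merged = nx.Graph()
    merged.add_nodes_from(sorted(common))
    for net in (net_a, net_b):
        merged.add_edges_from(
            (u, v) for u, v in net.edges() if u in common and v in common
        )
    return merged


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    degree_median: float
    degree_min: int
    degree_max: int


def network_summary(net: nx.Graph) -> NetworkSummary:
    """Node/edge counts and the degree median (even counts averaged)."""
    if net.number_of_nodes() == 0:
        return NetworkSummary(0, 0, 0.0, 0, 0)
    degrees = np.array([d for _, d in net.degree()])
    return NetworkSummary(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        degree_median=float(np.median(degrees)),
        degree_min=int(degrees.min()),
        degree_max=int(degrees.max()),
    )
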