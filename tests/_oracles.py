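"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take different routes from the package code: shortest
paths are enumerated with networkx generators, eigenvectors come from a
dense symmetric eigendecomposition, and the local-connectivity measures
are recomputed from triangle counts and adjacency-matrix algebra.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def bf_betweenness(g: nx.Graph) -> dict:
    """Betweenness by explicit enumeration of all shortest paths."""
    nodes = list(g)
    bc = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                if through:
                    bc[v] += through / len(paths)
    return bc


def bf_closeness(g: nx.Graph) -> dict:
    """Closeness with reachable-count numerator, via nx BFS lengths."""
    out = {}
    for v in g:
        lengths = nx.single_source_shortest_path_length(g, v)
        total = sum(lengths.values())
        out[v] = (len(lengths) - 1) / total if total > 0 else 0.0
    return out


def bf_eigenvector(g: nx.Graph) -> dict:
    """Principal eigenvector by dense eigendecomposition (connected g)."""
    nodes = sorted(g)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = v[:, np.argmax(w)]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)  # Perron vector of a connected graph is positive
    vec /= np.linalg.norm(vec)
    return dict(zip(nodes, vec))


def bf_lac(g: nx.Graph) -> dict:
    """LAC via triangle counts: 2 * triangles(v) / deg(v)."""
    tri = nx.triangles(g)
    return {
        v: (2.0 * tri[v] / d if (d := g.degree(v)) else 0.0) for v in g
    }


def bf_ncc(g: nx.Graph) -> dict:
    """NC via adjacency-matrix algebra: common neighbors from A @ A."""
    nodes = sorted(g)
    a = nx.to_numpy_array(g, nodelist=nodes)
    z = a @ a
    deg = a.sum(axis=1)
    out = dict.fromkeys(nodes, 0.0)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] == 0:
                continue
            denom = min(deg[i], deg[j]) - 1
            if denom > 0:
                ecc = z[i, j] / denom
                out[nodes[i]] += ecc
                out[nodes[j]] += ecc
    return out


def bf_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written directly from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted
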