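"""The six node-centrality measures used by the hub screen.

All six are implemented directly from their definitions on undirected,
unweighted, simple graphs:

* DC — degree centrality, the number of neighbors.
* BC — betweenness centrality, unnormalized, summed over unordered node
  pairs: ``bc(v) = sum_{s<t, s!=v!=t} sigma_st(v) / sigma_st`` where
  ``sigma_st`` counts shortest s-t paths.  Computed with Brandes'
  dependency-accumulation algorithm; unreachable pairs contribute zero.
* CC — closeness centrality, ``r_v / sum(d(v, u))`` over the nodes
  reachable from ``v`` (``r_v`` = their count, excluding ``v`` itself).
  Using the reachable count in the numerator keeps disconnected graphs
  finite; an isolated node scores 0.
* EC — eigenvector centrality: the principal eigenvector of the adjacency
  matrix, non-negative and normalized to unit Euclidean norm.
* LAC — local average connectivity: the mean degree of ``v``'s neighbors
  within the subgraph induced by ``N(v)``.
* NC — network centrality: the sum over edges incident to ``v`` of the
  edge clustering coefficient ``ECC(v, u) = z / min(deg(v)-1, deg(u)-1)``
  where ``z`` counts common neighbors of ``v`` and ``u``; a zero
  denominator makes the edge contribute nothing.

Node labels are arbitrary hashable strings; all outputs are plain dicts
keyed by node.  ``centrality_table`` assembles the six measures into one
deterministic, lexicographically ordered record list.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

__all__ = [
    "CentralityRecord",
    "degree_centrality",
    "betweenness",
    "closeness",
    "eigenvector",
    "lac",
    "ncc",
    "centrality_table",
    "write_centrality_table",
]


@dataclass(frozen=True)
class CentralityRecord:
    """The six centrality scores of one node."""

    node: str
    dc: int
    bc: float
    cc: float
    ec: float
    lac: float
    nc: float


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """DC: the degree of each node."""
    return {v: int(d) for v, d in net.degree()}


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness centrality over unordered node pairs.

    Brandes' single-source accumulation; each unordered pair is visited
    from both endpoints, so the accumulated totals are halved.  Nodes
    and adjacencies are traversed in sorted order so the floating-point
    accumulation (and hence the result, to the last bit) is independent
    of graph construction order.
    """
    order = sorted(net)
    adj = {v: sorted(net[v]) for v in order}
    bc = dict.fromkeys(order, 0.0)
    for s in order:
        stack: list = []
        preds: dict = {v: [] for v in order}
        sigma = dict.fromkeys(order, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            dv = dist[v]
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(order, 0.0)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return {v: b / 2.0 for v, b in bc.items()}


def closeness(net: nx.Graph) -> dict[str, float]:
    """Closeness with a reachable-count numerator (disconnection-safe)."""
    out = {}
    for v in net:
        total = 0
        reached = 0
        dist = {v: 0}
        queue = deque([v])
        while queue:
            u = queue.popleft()
            for w in net[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    total += dist[w]
                    reached += 1
                    queue.append(w)
        out[v] = reached / total if total > 0 else 0.0
    return out


def eigenvector(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, float]:
    """Principal-eigenvector centrality by power iteration.

    Iterates ``x <- (A + I) x`` from the uniform positive vector,
    renormalizing to unit Euclidean norm each step.  The identity shift
    leaves the eigenvectors unchanged but makes the dominant eigenvalue
    strictly largest in magnitude, so the iteration also converges on
    bipartite graphs, whose adjacency spectrum is symmetric.

    Raises ``RuntimeError`` (reporting the residual) if the max-norm
    change between successive iterates has not dropped below ``tol``
    within ``max_iter`` steps.  An edgeless graph yields all zeros with a
    warning; on a disconnected graph the mass concentrates on the
    dominant component and a warning is emitted.
    """
    if tol <= 0 or max_iter <= 0:
        raise ValueError("tol and max_iter must be positive")
    n = net.number_of_nodes()
    if n == 0:
        return {}
    if net.number_of_edges() == 0:
        warnings.warn("eigenvector centrality of an edgeless graph is all zeros")
        return {v: 0.0 for v in net}
    if not nx.is_connected(net):
        warnings.warn(
            "graph is disconnected; eigenvector mass concentrates on the "
            "dominant component"
        )
    nodes = sorted(net)
    a = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        x_new = a @ x + x
        x_new /= np.linalg.norm(x_new)
        residual = float(np.max(np.abs(x_new - x)))
        x = x_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} steps "
            f"(residual {residual:.3e} > tol {tol:.3e})"
        )
    x = np.clip(x, 0.0, None)
    x /= np.linalg.norm(x)
    return {v: float(s) for v, s in zip(nodes, x)}


def lac(net: nx.Graph) -> dict[str, float]:
    """Local average connectivity: mean neighbor degree inside G[N(v)]."""
    adj = {v: set(net[v]) for v in net}
    out = {}
    for v in net:
        nbrs = adj[v]
        if not nbrs:
            out[v] = 0.0
            continue
        # sum of induced degrees = twice the edge count among neighbors
        induced = sum(len(adj[u] & nbrs) for u in nbrs)
        out[v] = induced / len(nbrs)
    return out


def ncc(net: nx.Graph) -> dict[str, float]:
    """Network centrality: per-node sum of edge clustering coefficients.

    Edges are visited in sorted order so the floating-point sums do not
    depend on graph construction order.
    """
    adj = {v: set(net[v]) for v in net}
    out = dict.fromkeys(net, 0.0)
    for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
        denom = min(len(adj[u]), len(adj[v])) - 1
        if denom <= 0:
            continue
        z = len(adj[u] & adj[v])
        if z:
            ecc = z / denom
            out[u] += ecc
            out[v] += ecc
    return out


def centrality_table(net: nx.Graph, tol: float = 1e-10) -> list[CentralityRecord]:
    """All six measures for every node, in lexicographic node order."""
    dc = degree_centrality(net)
    bc = betweenness(net)
    cc = closeness(net)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ec = eigenvector(net, tol=tol) if net.number_of_nodes() else {}
    lac_ = lac(net)
    nc = ncc(net)
    return [
        CentralityRecord(
            node=v, dc=dc[v], bc=bc[v], cc=cc[v], ec=ec[v], lac=lac_[v], nc=nc[v]
        )
        for v in sorted(net)
    ]


def write_centrality_table(records: list[CentralityRecord], path) -> None:
    """Write a centrality table as a header-bearing TSV with stable order."""
    cols = [f.name for f in fields(CentralityRecord)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in sorted(records, key=lambda r: r.node):
            fh.write(
                f"{rec.node}\t{rec.dc}\t{rec.bc:.10g}\t{rec.cc:.10g}\t"
                f"{rec.ec:.10g}\t{rec.lac:.10g}\t{rec.nc:.10g}\n"
            )
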