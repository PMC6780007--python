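"""The two-stage topological screen that nominates candidate targets.

Stage 1 keeps the "significant" nodes of the merged network: those whose
degree strictly exceeds twice the network-wide median degree (the
doubling factor is configurable; 2.0 is the conventional choice).  Stage
2 recomputes all six centrality measures (DC, BC, CC, EC, LAC, NC) on
the stage-1 subnetwork, takes each measure's median over the subnetwork
nodes, and keeps the nodes that strictly exceed all six medians
simultaneously.  Strict comparisons mean nodes tied at a median are
excluded, so each stage keeps fewer than half of its input on typical
heavy-tailed networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .centrality import centrality_table

__all__ = [
    "ScreenResult",
    "stage1_cutoff",
    "stage1_significant",
    "stage2_candidates",
    "screen_targets",
]

MEASURES = ("dc", "bc", "cc", "ec", "lac", "nc")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the screen: surviving node sets and the thresholds used."""

    stage1_nodes: frozenset[str]
    stage1_cutoff: float
    stage2_nodes: frozenset[str]
    stage2_medians: dict[str, float] = field(default_factory=dict)


def stage1_cutoff(median_degree: float, factor: float = 2.0) -> float:
    """Degree cutoff of the first stage: ``factor`` times the median."""
    if median_degree < 0:
        raise ValueError(f"median degree must be >= 0, got {median_degree}")
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    return factor * median_degree


def stage1_significant(
    net: nx.Graph, factor: float = 2.0
) -> tuple[nx.Graph, float]:
    """Induced subgraph on nodes with degree > factor x median degree."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot screen an empty network")
    degrees = dict(net.degree())
    cutoff = stage1_cutoff(float(np.median(list(degrees.values()))), factor)
    kept = [v for v, d in degrees.items() if d > cutoff]
    return net.subgraph(kept).copy(), cutoff


def stage2_candidates(subnet: nx.Graph) -> ScreenResult:
    """Keep subnetwork nodes strictly above all six centrality medians.

    Centralities and their medians are computed on the subnetwork itself,
    not on the network it was extracted from.
    """
    if subnet.number_of_nodes() == 0:
        warnings.warn("stage-2 screen on an empty subnetwork")
        return ScreenResult(frozenset(), float("nan"), frozenset(), {})
    records = centrality_table(subnet)
    medians = {
        m: float(np.median([getattr(r, m) for r in records])) for m in MEASURES
    }
    kept = frozenset(
        r.node
        for r in records
        if all(getattr(r, m) > medians[m] for m in MEASURES)
    )
    return ScreenResult(
        stage1_nodes=frozenset(subnet),
        stage1_cutoff=float("nan"),
        stage2_nodes=kept,
        stage2_medians=medians,
    )


def screen_targets(merged: nx.Graph, factor: float = 2.0) -> ScreenResult:
    """Run both stages on the merged network and report every threshold."""
    if merged.number_of_nodes() == 0:
        warnings.warn("screening an empty merged network")
        return ScreenResult(frozenset(), float("nan"), frozenset(), {})
    subnet, cutoff = stage1_significant(merged, factor)
    stage2 = stage2_candidates(subnet) if subnet.number_of_nodes() else ScreenResult(
        frozenset(), cutoff, frozenset(), {}
    )
    return ScreenResult(
        stage1_nodes=frozenset(subnet),
        stage1_cutoff=cutoff,
        stage2_nodes=stage2.stage2_nodes,
        stage2_medians=stage2.stage2_medians,
    )
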