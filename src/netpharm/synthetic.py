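"""Synthetic inputs with the statistical structure the screen assumes.

The pipeline normally consumes database exports (a compound table with
ADME scores, a compound-to-target mapping, a curated protein-protein
interactome, a two-group expression series, and GO/KEGG-style gene-set
collections).  This module generates all five offline, with planted
ground truth, so every downstream stage is testable end to end:

* the interactome is grown by preferential attachment, giving the
  heavy-tailed degree distribution that a degree-driven hub screen
  presupposes;
* compound targets are sampled with a strong bias toward high-degree
  proteins, emulating the hub-enrichment of curated drug-target space;
* expression is Gaussian on the log2 scale with a planted mean shift for
  a chosen set of differential genes (half up, half down);
* gene sets are uniform draws except for a few planted terms that
  concentrate their members on a designated candidate gene set, so they
  are genuinely enriched.

Ground truth (planted differential genes, planted enriched terms, and
the planted hub genes — the top decile of interactome degree intersected
with the candidate gene pool) is recorded alongside the data.  All
generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil
from pathlib import Path

import networkx as nx
import numpy as np

from .compounds import (
    CompoundRecord,
    filter_adme,
    write_compounds,
    write_compound_targets,
)
from .deg import ExpressionMatrix, write_expression
from .enrichment import write_gmt
from .network_io import write_edge_list

import pandas as pd

__all__ = [
    "FixtureBundle",
    "gen_compound_library",
    "gen_interactome",
    "gen_expression",
    "gen_genesets",
    "default_bundle",
    "write_bundle",
]


@dataclass(frozen=True)
class FixtureBundle:
    """Every input the pipeline consumes, plus the planted ground truth."""

    compounds: list[CompoundRecord]
    compound_target_map: list[tuple[str, str]]
    interactome: nx.Graph
    expression: ExpressionMatrix
    genesets: dict[str, set[str]]
    truth: dict = field(default_factory=dict)


def _gene_symbol(i: int) -> str:
    return f"GENE{i:05d}"


def gen_compound_library(
    n_compounds: int, n_herbs: int, frac_pass: float, seed: int
) -> list[CompoundRecord]:
    """Random compound records with a forced ADME pass fraction.

    Exactly ``round(frac_pass * n_compounds)`` records satisfy OB >= 30
    and DL >= 0.18; scores are uniform on [0, 100] x [0, 1], forced to
    the wanted side of the threshold by rejection sampling.  Each record
    gets 1-3 source herbs uniformly.
    """
    if n_compounds < 1 or n_herbs < 1:
        raise ValueError("n_compounds and n_herbs must be positive")
    if not 0.0 <= frac_pass <= 1.0:
        raise ValueError(f"frac_pass {frac_pass} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = round(frac_pass * n_compounds)
    status = np.zeros(n_compounds, dtype=bool)
    status[:n_pass] = True
    rng.shuffle(status)
    herbs = [f"HRB{i + 1}" for i in range(n_herbs)]
    records = []
    for i, want_pass in enumerate(status):
        while True:
            ob = float(rng.uniform(0.0, 100.0))
            dl = float(rng.uniform(0.0, 1.0))
            if (ob >= 30.0 and dl >= 0.18) == want_pass:
                break
        k = int(rng.integers(1, min(3, n_herbs) + 1))
        sources = rng.choice(herbs, size=k, replace=False)
        records.append(
            CompoundRecord(
                compound_id=f"CMP{i + 1:04d}",
                name=f"synthetic-compound-{i + 1}",
                ob=round(ob, 2),
                dl=round(dl, 3),
                herbs=frozenset(sources.tolist()),
            )
        )
    return records


def gen_interactome(n_nodes: int, edges_per_node: int, seed: int) -> nx.Graph:
    """Scale-free background interactome by preferential attachment.

    Connected, simple, undirected; nodes are synthetic gene symbols.
    """
    if edges_per_node < 1:
        raise ValueError("edges_per_node must be >= 1")
    if n_nodes <= edges_per_node:
        raise ValueError(
            f"n_nodes ({n_nodes}) must exceed edges_per_node ({edges_per_node})"
        )
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=int(seed))
    return nx.relabel_nodes(g, {i: _gene_symbol(i) for i in g})


def gen_expression(
    n_genes: int,
    n_per_group: int,
    n_de: int,
    effect_log2: float,
    sigma: float,
    seed: int,
    genes: list[str] | None = None,
    de_pool: list[str] | None = None,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Gaussian log2 intensities with a planted two-group mean shift.

    ``n_de`` genes (drawn from ``de_pool``, default all genes) receive a
    case-group shift of ``effect_log2`` — half up, half down.  Baseline
    intensities are uniform on [4, 12] (typical microarray log2 range);
    noise is iid Normal(0, sigma).  Returns the matrix and a map from
    planted gene to shift direction (+1/-1).
    """
    if n_genes < 1 or n_per_group < 1:
        raise ValueError("n_genes and n_per_group must be positive")
    if effect_log2 <= 0 or sigma <= 0:
        raise ValueError("effect_log2 and sigma must be positive")
    if genes is None:
        genes = [_gene_symbol(i) for i in range(n_genes)]
    if len(genes) != n_genes or len(set(genes)) != n_genes:
        raise ValueError("genes must be n_genes unique symbols")
    if de_pool is None:
        de_pool = genes
    if n_de > len(de_pool):
        raise ValueError(f"n_de ({n_de}) exceeds the DE pool ({len(de_pool)})")
    rng = np.random.default_rng(seed)
    samples = [f"CASE{i + 1}" for i in range(n_per_group)] + [
        f"CTRL{i + 1}" for i in range(n_per_group)
    ]
    groups = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, sigma, size=(n_genes, 2 * n_per_group)
    )
    chosen = rng.choice(sorted(de_pool), size=n_de, replace=False)
    directions = {}
    index = {g: i for i, g in enumerate(genes)}
    for j, gene in enumerate(chosen):
        sign = 1 if j < ceil(n_de / 2) else -1
        values[index[gene], :n_per_group] += sign * effect_log2
        directions[str(gene)] = sign
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
    )
    return matrix, directions


def gen_genesets(
    universe: set[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    planted_terms: int,
    candidate_genes: set[str],
    seed: int,
) -> tuple[dict[str, set[str]], list[str]]:
    """Random gene sets with a few terms planted to enrich.

    Planted terms draw at least 60% (target fraction 0.7) of their
    members from ``candidate_genes``; the rest, and all non-planted
    terms, are uniform draws from the universe.  Returns the collection
    and the planted term ids.
    """
    universe = sorted(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if n_terms < 0 or planted_terms < 0 or planted_terms > n_terms:
        raise ValueError("need 0 <= planted_terms <= n_terms")
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"term sizes {term_size_range} incompatible with universe")
    rng = np.random.default_rng(seed)
    candidates = sorted(set(candidate_genes) & set(universe))
    sets: dict[str, set[str]] = {}
    planted_ids = []
    for t in range(n_terms):
        term_id = f"TERM{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if t < planted_terms:
            n_cand = min(len(candidates), ceil(0.7 * size))
            members = set(rng.choice(candidates, size=n_cand, replace=False))
            rest = [g for g in universe if g not in members]
            members |= set(rng.choice(rest, size=size - n_cand, replace=False))
            planted_ids.append(term_id)
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        sets[term_id] = {str(m) for m in members}
    return sets, planted_ids


# ---------------------------------------------------------------------------
# the default study fixture


def default_bundle(
    seed: int,
    n_nodes: int = 1000,
    edges_per_node: int = 3,
    rich_club_size: int = 30,
    rich_club_p: float = 0.5,
    n_compounds: int = 60,
    n_herbs: int = 9,
    frac_pass: float = 0.7,
    n_genes: int = 1000,
    n_per_group: int = 5,
    n_de: int = 200,
    effect_log2: float = 3.0,
    sigma: float = 0.3,
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (10, 40),
    planted_terms: int = 3,
) -> FixtureBundle:
    """Assemble the default study fixture from one master seed.

    The interactome is a preferential-attachment graph augmented with a
    rich club: the ``rich_club_size`` highest-degree proteins are
    additionally wired to each other with probability ``rich_club_p``,
    emulating the dense hub core of curated interactomes.  Compound
    targets combine a degree-squared-weighted draw from the non-hub tier
    with a few "famous" targets per compound from the rich club,
    emulating how curated drug-target space concentrates on well-studied
    central proteins.  Planted differential genes are drawn from the
    interactome's non-hub genes present on the expression chip.  The
    planted hub truth is the top decile of interactome degree intersected
    with the pooled candidate genes (compound targets plus planted
    differential genes), which by construction is essentially the rich
    club; the planted enriched terms concentrate their members on that
    hub set.
    """
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=8)
    interactome = gen_interactome(n_nodes, edges_per_node, int(child[0]))
    compounds = gen_compound_library(n_compounds, n_herbs, frac_pass, int(child[1]))

    rng = np.random.default_rng(int(child[2]))
    degrees = dict(interactome.degree())
    nodes = sorted(interactome)
    club = sorted(nodes, key=lambda v: (-degrees[v], v))[:rich_club_size]
    for u, v in combinations(club, 2):
        if not interactome.has_edge(u, v) and rng.random() < rich_club_p:
            interactome.add_edge(u, v)
    degrees = dict(interactome.degree())
    deg_arr = np.array([degrees[v] for v in nodes], dtype=float)
    decile_cut = float(np.percentile(deg_arr, 90))
    top_decile = {v for v in nodes if degrees[v] > decile_cut}

    passing = filter_adme(compounds)
    non_hub = [v for v in nodes if v not in top_decile]
    weights = np.array([degrees[v] ** 2 for v in non_hub], dtype=float)
    weights /= weights.sum()
    mapping: set[tuple[str, str]] = set()
    mapped_compounds = passing[: max(1, round(0.9 * len(passing)))]
    for rec in mapped_compounds:
        n_t = int(rng.integers(3, 19))
        targets = rng.choice(non_hub, size=n_t, replace=False, p=weights)
        n_hub = int(rng.integers(2, 6))
        famous = rng.choice(club, size=min(n_hub, len(club)), replace=False)
        for gene in list(targets) + list(famous):
            mapping.add((rec.compound_id, str(gene)))

    # expression chip: mostly interactome genes, DE planted off the hub tier
    n_on_chip = round(0.95 * n_genes)
    chip_genes = list(rng.choice(nodes, size=n_on_chip, replace=False))
    chip_genes += [_gene_symbol(n_nodes + i) for i in range(n_genes - n_on_chip)]
    chip_genes = sorted(str(g) for g in chip_genes)
    de_pool = sorted(set(chip_genes) & (set(nodes) - top_decile))
    expression, de_directions = gen_expression(
        n_genes,
        n_per_group,
        n_de,
        effect_log2,
        sigma,
        int(child[3]),
        genes=chip_genes,
        de_pool=de_pool,
    )

    candidate_pool = {g for _, g in mapping} | set(de_directions)
    planted_hubs = sorted(top_decile & candidate_pool)
    universe = set(chip_genes) | {g for _, g in mapping}
    genesets, planted_ids = gen_genesets(
        universe,
        n_terms,
        term_size_range,
        planted_terms,
        set(planted_hubs),
        int(child[4]),
    )
    truth = {
        "planted_de": sorted(de_directions),
        "planted_de_direction": dict(sorted(de_directions.items())),
        "planted_terms": planted_ids,
        "planted_hubs": planted_hubs,
    }
    return FixtureBundle(
        compounds=compounds,
        compound_target_map=sorted(mapping),
        interactome=interactome,
        expression=expression,
        genesets=genesets,
        truth=truth,
    )


def write_bundle(bundle: FixtureBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as six plain-text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compounds.tsv",
        "compound_targets": out / "compound_targets.tsv",
        "interactome": out / "interactome.edges",
        "expression": out / "expression.tsv",
        "genesets": out / "genesets.gmt",
        "truth": out / "truth.json",
    }
    write_compounds(bundle.compounds, paths["compounds"])
    write_compound_targets(bundle.compound_target_map, paths["compound_targets"])
    write_edge_list(bundle.interactome, paths["interactome"])
    write_expression(bundle.expression, paths["expression"])
    write_gmt(bundle.genesets, paths["genesets"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
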