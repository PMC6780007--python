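"""Over-representation analysis and the gene-pathway core-gene ranking.

Candidate genes are tested term-by-term against flat gene-set
collections (GO/KEGG-style, GMT files) with the upper-tail
hypergeometric test: for a universe of ``N`` annotated genes, a term of
size ``K``, a query of size ``n`` and an overlap of ``k``, the p-value
is ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``, evaluated by exact
combinatorial summation.  The conservative EASE variant (overlap reduced
by one before testing, as popularized by the DAVID service) is available
as a flag.  P-values are corrected with Benjamini-Hochberg step-up FDR.

Significant terms and their overlapping genes form a bipartite
gene-pathway network; the "core gene" of the analysis is the gene with
the largest betweenness centrality in that network (ties broken
lexicographically).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import networkx as nx
from statsmodels.stats.multitest import multipletests

from .centrality import betweenness

__all__ = [
    "EnrichmentRecord",
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich",
    "build_gene_pathway_network",
    "rank_core_genes",
    "read_gmt",
    "write_gmt",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One gene-set test: counts, hypergeometric p, BH-FDR q."""

    term_id: str
    term_size: int  # K: universe genes annotated to the term
    query_size: int  # n
    overlap: int  # k
    universe_size: int  # N
    pvalue: float
    fdr: float
    overlap_genes: frozenset[str]

    @property
    def significant(self) -> bool:
        return self.fdr < 0.05


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), exactly.

    X counts the annotated genes in a size-``n`` draw without replacement
    from a universe of ``N`` genes of which ``K`` are annotated.  The sum
    is carried out in exact integer arithmetic and converted to float at
    the end.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    numerator = sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)
    )
    return float(Fraction(numerator, comb(N, n)))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input-order aligned."""
    if any(not 0.0 <= p <= 1.0 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    if not pvalues:
        return []
    return list(multipletests(pvalues, method="fdr_bh")[1])


def enrich(
    query: set[str],
    genesets: dict[str, set[str]],
    universe: set[str] | None = None,
    fdr_max: float = 0.05,
    top_k: int | None = None,
    ease: bool = False,
) -> list[EnrichmentRecord]:
    """Test the query against every term; report overlapping terms only.

    The universe defaults to all genes annotated in the collection.  Query
    genes outside the universe are dropped with a warning; term members
    are intersected with the universe.  One record is produced per term
    with overlap >= 1, sorted by (pvalue, term_id); ``top_k`` truncates
    after sorting.  ``ease`` applies the conservative overlap-minus-one
    convention.  BH correction spans the reported (overlapping) terms.
    """
    if universe is None:
        universe = set().union(*genesets.values()) if genesets else set()
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped "
            f"(e.g. {sorted(outside)[:3]})"
        )
    query &= universe
    N, n = len(universe), len(query)
    tested = []
    for term_id in sorted(genesets):
        members = set(genesets[term_id]) & universe
        hits = query & members
        if not hits:
            continue
        k, K = len(hits), len(members)
        k_eff = max(k - 1, 0) if ease else k
        tested.append(
            (term_id, K, k, hypergeom_pvalue(k_eff, n, K, N), frozenset(hits))
        )
    fdrs = bh_adjust([t[3] for t in tested])
    records = [
        EnrichmentRecord(
            term_id=term_id,
            term_size=K,
            query_size=n,
            overlap=k,
            universe_size=N,
            pvalue=p,
            fdr=float(q),
            overlap_genes=hits,
        )
        for (term_id, K, k, p, hits), q in zip(tested, fdrs)
    ]
    records.sort(key=lambda r: (r.pvalue, r.term_id))
    if top_k is not None:
        records = records[:top_k]
    return records


def build_gene_pathway_network(records: list[EnrichmentRecord]) -> nx.Graph:
    """Bipartite network joining each pathway to its overlapping genes.

    Nodes carry ``kind`` = "pathway" or "gene".  Pass only the records
    meant to appear (e.g. the FDR-significant ones).
    """
    g = nx.Graph()
    for rec in records:
        g.add_node(rec.term_id, kind="pathway")
        for gene in sorted(rec.overlap_genes):
            g.add_node(gene, kind="gene")
            g.add_edge(rec.term_id, gene)
    return g


def rank_core_genes(net: nx.Graph) -> list[tuple[str, float]]:
    """Genes of the gene-pathway network by betweenness, descending.

    Ties break lexicographically; the head of the list is the core gene.
    """
    if net.number_of_nodes() == 0:
        return []
    bc = betweenness(net)
    genes = [v for v, data in net.nodes(data=True) if data.get("kind") == "gene"]
    return sorted(((g, bc[g]) for g in genes), key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# file formats


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT collection: term, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            term, _desc, *members = parts
            if term in sets:
                raise ValueError(f"duplicate GMT term {term!r}")
            sets[term] = {m for m in members if m}
    return sets


def write_gmt(
    genesets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(genesets):
            desc = descriptions.get(term, "na")
            members = "\t".join(sorted(genesets[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def write_enrichment_table(records: list[EnrichmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\toverlap\tterm_size\tquery_size\tuniverse_size\t"
                 "pvalue\tfdr\toverlap_genes\n")
        for r in records:
            genes = ",".join(sorted(r.overlap_genes))
            fh.write(
                f"{r.term_id}\t{r.overlap}\t{r.term_size}\t{r.query_size}\t"
                f"{r.universe_size}\t{r.pvalue:.6g}\t{r.fdr:.6g}\t{genes}\n"
            )
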