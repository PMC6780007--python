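"""Compound library screening and the bipartite compound-target network.

A multi-herb formula is described by a table of candidate compounds, each
carrying a TCMSP-style oral bioavailability (OB, percent) and
drug-likeness (DL, unitless) score plus the herbs it derives from.  The
screen retains compounds with OB >= 30 and DL >= 0.18 (inclusive, both
arms), with a whitelist mechanism for compounds kept on external
pharmacological evidence despite sub-threshold scores.  Duplicated
entries across herbs are merged, compounds mapping to no target are
dropped, and the surviving compounds and their targets form an
undirected bipartite network.

A reference compound table for the nine-herb Yiqi Shexue (YQSX) formula
ships with the package, together with the whitelist of its sub-threshold
compounds (literature-supported actives and the amino acids of
donkey-hide gelatin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

DEFAULT_OB_MIN = 30.0
DEFAULT_DL_MIN = 0.18

#: A compound->target mapping is any iterable of (compound_id, gene_symbol)
#: pairs; duplicates are ignored everywhere.
CompoundTargetMap = Iterable[tuple[str, str]]

__all__ = [
    "CompoundRecord",
    "filter_adme",
    "dedupe_library",
    "drop_orphans",
    "build_compound_target_network",
    "per_herb_target_counts",
    "HerbTargetCounts",
    "read_compounds",
    "write_compounds",
    "read_compound_targets",
    "write_compound_targets",
    "read_whitelist",
    "load_reference_compounds",
    "load_reference_whitelist",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One formula ingredient with its ADME scores and herb provenance."""

    compound_id: str
    name: str
    ob: float
    dl: float
    herbs: frozenset[str]

    def __post_init__(self):
        if not self.herbs:
            raise ValueError(f"{self.compound_id}: herb set must be non-empty")
        if not 0.0 <= self.ob <= 100.0:
            raise ValueError(f"{self.compound_id}: OB {self.ob} outside [0, 100]")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.compound_id}: DL {self.dl} outside [0, 1]")


def filter_adme(
    library: list[CompoundRecord],
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
    whitelist: frozenset[str] | set[str] = frozenset(),
) -> list[CompoundRecord]:
    """Keep compounds with OB >= ob_min and DL >= dl_min, or whitelisted.

    Comparisons are inclusive; input order is preserved.
    """
    if not 0.0 <= ob_min <= 100.0:
        raise ValueError(f"ob_min {ob_min} outside [0, 100]")
    if not 0.0 <= dl_min <= 1.0:
        raise ValueError(f"dl_min {dl_min} outside [0, 1]")
    whitelist = frozenset(whitelist)
    return [
        r
        for r in library
        if (r.ob >= ob_min and r.dl >= dl_min) or r.compound_id in whitelist
    ]


def dedupe_library(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse duplicate compound ids, unioning their herb sources.

    The first-seen name/OB/DL are kept; conflicting scores for one id are
    logged as a warning.  Idempotent; first-seen order preserved.
    """
    merged: dict[str, CompoundRecord] = {}
    for rec in records:
        prev = merged.get(rec.compound_id)
        if prev is None:
            merged[rec.compound_id] = rec
            continue
        if (prev.ob, prev.dl) != (rec.ob, rec.dl):
            logger.warning(
                "conflicting OB/DL for %s: keeping first-seen (%s, %s), "
                "ignoring (%s, %s)",
                rec.compound_id, prev.ob, prev.dl, rec.ob, rec.dl,
            )
        merged[rec.compound_id] = replace(prev, herbs=prev.herbs | rec.herbs)
    return list(merged.values())


def drop_orphans(
    records: list[CompoundRecord], mapping: CompoundTargetMap
) -> list[CompoundRecord]:
    """Drop compounds that map to no target at all."""
    mapped = {cid for cid, _ in mapping}
    return [r for r in records if r.compound_id in mapped]


def build_compound_target_network(
    records: list[CompoundRecord], mapping: CompoundTargetMap
) -> nx.Graph:
    """Bipartite compound-target network: one edge per unique pair.

    Nodes carry a ``kind`` attribute ("compound" or "target"); compound
    nodes also carry their herb sources.  A mapping pair referencing a
    compound id not present in ``records`` is an error.
    """
    by_id = {r.compound_id: r for r in records}
    pairs = sorted(set(map(tuple, mapping)))
    for cid, _ in pairs:
        if cid not in by_id:
            raise ValueError(f"mapping references unknown compound id {cid!r}")
    targets = sorted({g for _, g in pairs})
    clash = set(by_id) & set(targets)
    if clash:
        raise ValueError(f"labels used as both compound and target: {sorted(clash)}")
    g = nx.Graph()
    for r in records:
        g.add_node(r.compound_id, kind="compound", herbs=tuple(sorted(r.herbs)))
    for t in targets:
        g.add_node(t, kind="target")
    g.add_edges_from(pairs)
    return g


@dataclass(frozen=True)
class HerbTargetCounts:
    """Per-herb tallies of compound-target pairs.

    ``per_herb[h]`` counts the unique (compound, target) pairs whose
    compound lists herb ``h`` as a source; a compound sourced from
    several herbs is tallied once under each of them, so ``total`` (the
    sum over herbs) can exceed ``unique_pairs``, the plain count of
    distinct pairs (the compound-target network's edge count).
    """

    per_herb: dict[str, int]
    total: int
    unique_pairs: int


def per_herb_target_counts(
    records: list[CompoundRecord], mapping: CompoundTargetMap
) -> HerbTargetCounts:
    """Tally compound-target pairs by source herb (see HerbTargetCounts)."""
    herbs_of = {r.compound_id: r.herbs for r in records}
    pairs = {tuple(p) for p in mapping if p[0] in herbs_of}
    counts: dict[str, int] = {h: 0 for r in records for h in r.herbs}
    for cid, _ in pairs:
        for h in herbs_of[cid]:
            counts[h] += 1
    return HerbTargetCounts(
        per_herb=dict(sorted(counts.items())),
        total=sum(counts.values()),
        unique_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# file formats


def read_compounds(path) -> list[CompoundRecord]:
    """Read a compound TSV: compound_id, name, ob, dl, herbs (comma list)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["compound_id", "name", "ob", "dl", "herbs"]
        if header != expected:
            raise ValueError(f"bad compound table header {header}; want {expected}")
        for line in fh:
            if not line.strip():
                continue
            cid, name, ob, dl, herbs = line.rstrip("\n").split("\t")
            out.append(
                CompoundRecord(
                    compound_id=cid,
                    name=name,
                    ob=float(ob),
                    dl=float(dl),
                    herbs=frozenset(h for h in herbs.split(",") if h),
                )
            )
    return out


def write_compounds(records: list[CompoundRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tname\tob\tdl\therbs\n")
        for r in records:
            herbs = ",".join(sorted(r.herbs))
            fh.write(f"{r.compound_id}\t{r.name}\t{r.ob:g}\t{r.dl:g}\t{herbs}\n")


def read_compound_targets(path) -> list[tuple[str, str]]:
    """Read a compound_id/gene_symbol TSV into a sorted unique pair list."""
    pairs = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["compound_id", "gene_symbol"]:
            raise ValueError(f"bad compound-target header {header}")
        for line in fh:
            if not line.strip():
                continue
            cid, gene = line.rstrip("\n").split("\t")
            pairs.add((cid, gene))
    return sorted(pairs)


def write_compound_targets(mapping: CompoundTargetMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tgene_symbol\n")
        for cid, gene in sorted(set(map(tuple, mapping))):
            fh.write(f"{cid}\t{gene}\n")


def read_whitelist(path) -> frozenset[str]:
    """One compound id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return frozenset(
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        )


def _data_path(name: str):
    return resources.files("netpharm.data").joinpath(name)


def load_reference_compounds() -> list[CompoundRecord]:
    """The packaged YQSX formula compound table (148 compounds, 9 herbs)."""
    with resources.as_file(_data_path("yqsx_compounds.tsv")) as p:
        return read_compounds(p)


def load_reference_whitelist() -> frozenset[str]:
    """Whitelist of packaged compounds kept despite sub-threshold OB/DL."""
    with resources.as_file(_data_path("yqsx_whitelist.txt")) as p:
        return read_whitelist(p)
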