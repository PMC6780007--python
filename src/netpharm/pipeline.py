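"""End-to-end orchestration: files in, screened targets and report out.

``run_pipeline`` executes the full analysis from a declarative YAML
config: compound filtering -> compound-target network -> differential
expression -> one-hop PPI expansion of both seed sets -> intersection
merge -> two-stage six-centrality screen -> enrichment -> gene-pathway
core-gene ranking.  Every intermediate artifact is written under the
output directory, and a machine-readable JSON run report collects the
counts, thresholds, and medians of every stage.  Errors are attributed
to the stage that raised them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import compounds as cmp
from . import deg as degmod
from . import enrichment as enr
from . import ppi as ppimod
from . import screening as scr
from .network_io import read_edge_list, write_edge_list, write_sif
from .synthetic import default_bundle, write_bundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_fixtures"]


class PipelineError(RuntimeError):
    """An error attributed to a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Thresholds default to the conventional values of the screening
    procedure: OB >= 30, DL >= 0.18, p < 0.005, |log2fc| > 1, stage-1
    doubling factor 2, FDR < 0.05, top 20 terms reported.
    """

    compounds: str
    compound_targets: str
    interactome: str
    expression: str
    genesets: str
    groups: dict[str, str]
    out_dir: str = "run"
    whitelist: str | None = None
    ob_min: float = 30.0
    dl_min: float = 0.18
    p_max: float = 0.005
    lfc_min: float = 1.0
    log2_transform: bool = False
    expansion_depth: int = 1
    stage1_factor: float = 2.0
    fdr_max: float = 0.05
    top_k: int | None = 20
    ease: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name):
    """Decorator re-raising stage failures as stage-attributed errors."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - attribute and re-raise
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


@_stage("compound_screen")
def _run_compounds(config: PipelineConfig, out: Path):
    library = cmp.read_compounds(config.compounds)
    whitelist = (
        cmp.read_whitelist(config.whitelist) if config.whitelist else frozenset()
    )
    filtered = cmp.filter_adme(library, config.ob_min, config.dl_min, whitelist)
    deduped = cmp.dedupe_library(filtered)
    mapping = cmp.read_compound_targets(config.compound_targets)
    retained = cmp.drop_orphans(deduped, mapping)
    kept_ids = {r.compound_id for r in retained}
    mapping = [(c, g) for c, g in mapping if c in kept_ids]
    network = cmp.build_compound_target_network(retained, mapping)
    herb_counts = cmp.per_herb_target_counts(retained, mapping)
    cmp.write_compounds(retained, out / "compounds_retained.tsv")
    write_sif(network, out / "compound_target_network.sif")
    targets = sorted({g for _, g in mapping})
    counts = {
        "n_input": len(library),
        "n_filtered": len(filtered),
        "n_deduped": len(deduped),
        "n_retained": len(retained),
        "n_pairs": len(set(mapping)),
        "n_unique_targets": len(targets),
        "per_herb_pairs": herb_counts.per_herb,
    }
    logger.info("compound_screen: %s", counts)
    return targets, counts


@_stage("deg_analysis")
def _run_degs(config: PipelineConfig, out: Path):
    matrix = degmod.read_expression(
        config.expression, config.groups, log2_transform=config.log2_transform
    )
    records = degmod.call_degs(matrix, p_max=config.p_max, lfc_min=config.lfc_min)
    degmod.write_deg_table(records, out / "deg_table.tsv")
    degmod.volcano_table(records).to_csv(
        out / "volcano.tsv", sep="\t", index=False, float_format="%.6g"
    )
    deg_genes = sorted(r.gene for r in records if r.is_deg)
    counts = {"n_genes": len(records), "n_deg": len(deg_genes)}
    logger.info("deg_analysis: %s", counts)
    return deg_genes, counts


@_stage("ppi")
def _run_networks(config: PipelineConfig, out: Path, targets, deg_genes):
    interactome = read_edge_list(config.interactome)
    if interactome.number_of_nodes() == 0:
        raise ValueError(f"interactome {config.interactome} is empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net_a = ppimod.expand_seeds(
            set(targets), interactome, depth=config.expansion_depth
        )
        net_b = ppimod.expand_seeds(
            set(deg_genes), interactome, depth=config.expansion_depth
        )
    merged = ppimod.merge_networks(net_a, net_b)
    write_edge_list(merged, out / "merged_network.edges")
    summaries = {
        name: asdict(ppimod.network_summary(net))
        for name, net in (
            ("interactome", interactome),
            ("formula_targets", net_a),
            ("disease_targets", net_b),
            ("merged", merged),
        )
    }
    logger.info("ppi: %s", {k: v["n_nodes"] for k, v in summaries.items()})
    return merged, summaries


@_stage("screening")
def _run_screen(config: PipelineConfig, out: Path, merged):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = scr.screen_targets(merged, factor=config.stage1_factor)
    report = {
        "stage1_cutoff": result.stage1_cutoff,
        "n_stage1": len(result.stage1_nodes),
        "n_stage2": len(result.stage2_nodes),
        "stage2_medians": result.stage2_medians,
    }
    with open(out / "screen_report.json", "w") as fh:
        json.dump(
            {
                **report,
                "stage1_nodes": sorted(result.stage1_nodes),
                "stage2_nodes": sorted(result.stage2_nodes),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    with open(out / "candidate_targets.tsv", "w") as fh:
        fh.write("gene\n")
        for gene in sorted(result.stage2_nodes):
            fh.write(gene + "\n")
    logger.info("screening: %s", report)
    return result, report


@_stage("enrichment")
def _run_enrichment(config: PipelineConfig, out: Path, candidates):
    genesets = enr.read_gmt(config.genesets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = enr.enrich(
            set(candidates),
            genesets,
            fdr_max=config.fdr_max,
            top_k=None,
            ease=config.ease,
        )
    enr.write_enrichment_table(records, out / "enrichment.tsv")
    significant = [r for r in records if r.fdr < config.fdr_max]
    reported = records[: config.top_k] if config.top_k else records
    gp_net = enr.build_gene_pathway_network(significant)
    write_sif(gp_net, out / "gene_pathway_network.sif")
    ranking = enr.rank_core_genes(gp_net)
    with open(out / "core_genes.tsv", "w") as fh:
        fh.write("gene\tbetweenness\n")
        for gene, bc in ranking:
            fh.write(f"{gene}\t{bc:.6g}\n")
    counts = {
        "n_terms_tested": len(records),
        "n_significant": len(significant),
        "n_reported": len(reported),
        "core_gene": ranking[0][0] if ranking else None,
        "top_genes": [g for g, _ in ranking[:6]],
    }
    logger.info("enrichment: %s", counts)
    return counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write artifacts and the JSON run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets, compound_counts = _run_compounds(config, out)
    deg_genes, deg_counts = _run_degs(config, out)
    merged, net_summaries = _run_networks(config, out, targets, deg_genes)
    result, screen_report = _run_screen(config, out, merged)
    enrich_counts = _run_enrichment(config, out, sorted(result.stage2_nodes))
    report = {
        "params": {
            k: v
            for k, v in asdict(config).items()
            if k not in {"groups", "out_dir"}
        },
        "stages": {
            "compound_screen": compound_counts,
            "deg_analysis": deg_counts,
            "networks": net_summaries,
            "screening": screen_report,
            "enrichment": enrich_counts,
        },
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def make_fixtures(seed: int, out_dir) -> dict:
    """Write the default synthetic bundle plus the packaged reference data.

    Produces the six bundle files, the reference compound table and
    whitelist, and a ready-to-run ``config.yaml`` wired to the synthetic
    inputs.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = default_bundle(seed)
    paths = write_bundle(bundle, out)
    reference = cmp.load_reference_compounds()
    cmp.write_compounds(reference, out / "yqsx_compounds.tsv")
    with open(out / "yqsx_whitelist.txt", "w") as fh:
        for cid in sorted(cmp.load_reference_whitelist()):
            fh.write(cid + "\n")
    config = PipelineConfig(
        compounds=str(paths["compounds"]),
        compound_targets=str(paths["compound_targets"]),
        interactome=str(paths["interactome"]),
        expression=str(paths["expression"]),
        genesets=str(paths["genesets"]),
        groups=dict(bundle.expression.groups),
        out_dir=str(out / "run"),
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    paths.update(
        {
            "reference_compounds": out / "yqsx_compounds.tsv",
            "reference_whitelist": out / "yqsx_whitelist.txt",
            "config": out / "config.yaml",
        }
    )
    return {k: str(v) for k, v in paths.items()}
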