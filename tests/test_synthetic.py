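"""Generators: forced structure, determinism, and planted-signal recovery."""

import warnings

import networkx as nx
import numpy as np
import pytest

from netpharm import (
    call_degs,
    dedupe_library,
    drop_orphans,
    expand_seeds,
    filter_adme,
    merge_networks,
    screen_targets,
)
from netpharm.synthetic import (
    default_bundle,
    gen_compound_library,
    gen_expression,
    gen_genesets,
    gen_interactome,
    write_bundle,
)


def run_screen(bundle):
    """The in-memory pipeline up to the candidate target set."""
    lib = drop_orphans(
        dedupe_library(filter_adme(bundle.compounds)), bundle.compound_target_map
    )
    kept = {r.compound_id for r in lib}
    targets = {g for c, g in bundle.compound_target_map if c in kept}
    degs = {r.gene for r in call_degs(bundle.expression) if r.is_deg}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        merged = merge_networks(
            expand_seeds(targets, bundle.interactome),
            expand_seeds(degs, bundle.interactome),
        )
        return screen_targets(merged)


class TestCompoundLibrary:
    def test_pass_fraction_is_forced(self):
        lib = gen_compound_library(10, 2, 0.5, seed=1)
        passing = [r for r in lib if r.ob >= 30 and r.dl >= 0.18]
        assert len(passing) == 5

    def test_all_fail_when_fraction_zero(self):
        (rec,) = gen_compound_library(1, 1, 0.0, seed=7)
        assert rec.ob < 30 or rec.dl < 0.18

    def test_filter_retains_exactly_the_forced_passes(self):
        lib = gen_compound_library(200, 9, 0.8, seed=42)
        assert len(filter_adme(lib)) == 160

    def test_herb_sources_between_one_and_three(self):
        lib = gen_compound_library(50, 9, 0.5, seed=3)
        assert all(1 <= len(r.herbs) <= 3 for r in lib)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_compound_library(0, 2, 0.5, seed=1)
        with pytest.raises(ValueError):
            gen_compound_library(5, 0, 0.5, seed=1)
        with pytest.raises(ValueError):
            gen_compound_library(5, 2, 1.5, seed=1)

    def test_deterministic_per_seed(self):
        assert gen_compound_library(20, 3, 0.4, 11) == gen_compound_library(20, 3, 0.4, 11)
        assert gen_compound_library(20, 3, 0.4, 11) != gen_compound_library(20, 3, 0.4, 12)


class TestInteractome:
    def test_m1_yields_a_tree(self):
        g = gen_interactome(5, 1, seed=1)
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 4
        assert nx.is_connected(g)

    def test_heavy_tailed_degrees(self):
        g = gen_interactome(500, 3, seed=3)
        degrees = sorted(d for _, d in g.degree())
        assert max(degrees) > 3 * np.median(degrees)

    def test_max_exceeds_median_for_modest_sizes(self):
        for seed in range(3):
            g = gen_interactome(50, 2, seed=seed)
            degrees = [d for _, d in g.degree()]
            assert max(degrees) > np.median(degrees)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            gen_interactome(3, 5, seed=0)

    def test_simple_connected_and_deterministic(self):
        g1 = gen_interactome(100, 2, seed=5)
        g2 = gen_interactome(100, 2, seed=5)
        assert nx.utils.graphs_equal(g1, g2)
        assert nx.is_connected(g1)
        assert nx.number_of_selfloops(g1) == 0


class TestExpression:
    def test_null_case_has_no_planted_genes(self):
        matrix, directions = gen_expression(100, 3, 0, 2.0, 0.3, seed=5)
        assert directions == {}
        assert matrix.values.shape == (100, 6)

    def test_planted_split_half_up_half_down(self):
        _, directions = gen_expression(200, 4, 20, 3.0, 0.3, seed=2)
        signs = list(directions.values())
        assert signs.count(1) == 10 and signs.count(-1) == 10

    def test_planted_shift_visible_in_group_means(self):
        matrix, directions = gen_expression(50, 50, 10, 3.0, 0.1, seed=6)
        case, ctrl = matrix.case_samples, matrix.control_samples
        for gene, sign in directions.items():
            diff = (
                matrix.values.loc[gene, case].mean()
                - matrix.values.loc[gene, ctrl].mean()
            )
            assert diff == pytest.approx(3.0 * sign, abs=0.2)

    def test_overfull_de_set_rejected(self):
        with pytest.raises(ValueError):
            gen_expression(10, 2, 20, 2.0, 0.3, seed=1)

    def test_deterministic_per_seed(self):
        m1, d1 = gen_expression(50, 3, 5, 2.0, 0.3, seed=9)
        m2, d2 = gen_expression(50, 3, 5, 2.0, 0.3, seed=9)
        assert d1 == d2
        assert m1.values.equals(m2.values)


class TestGenesets:
    def test_planted_terms_draw_from_candidates(self):
        universe = {f"g{i}" for i in range(500)}
        candidates = {f"g{i}" for i in range(50)}
        sets, planted = gen_genesets(universe, 20, (10, 40), 3, candidates, seed=2)
        assert len(planted) == 3
        assert len(sets) == 20
        for term in planted:
            frac = len(sets[term] & candidates) / len(sets[term])
            assert frac >= 0.6
        for term, members in sets.items():
            assert members <= universe

    def test_no_terms_yields_empty_collection(self):
        sets, planted = gen_genesets({"a", "b"}, 0, (1, 2), 0, set(), seed=1)
        assert sets == {} and planted == []

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gen_genesets(set(), 5, (1, 2), 0, set(), seed=1)

    def test_planted_cannot_exceed_terms(self):
        with pytest.raises(ValueError):
            gen_genesets({"a", "b", "c"}, 2, (1, 2), 3, {"a"}, seed=1)


class TestDefaultBundle:
    def test_truth_sets_are_subsets_of_their_universes(self, bundle):
        genes = set(bundle.expression.genes)
        assert set(bundle.truth["planted_de"]) <= genes
        assert set(bundle.truth["planted_terms"]) <= set(bundle.genesets)
        assert set(bundle.truth["planted_hubs"]) <= set(bundle.interactome)

    def test_mapped_and_measured_genes_mostly_in_interactome(self, bundle):
        nodes = set(bundle.interactome)
        targets = {g for _, g in bundle.compound_target_map}
        assert targets <= nodes
        genes = set(bundle.expression.genes)
        assert len(genes & nodes) / len(genes) >= 0.8

    def test_bit_reproducible(self):
        b1, b2 = default_bundle(3), default_bundle(3)
        assert b1.compound_target_map == b2.compound_target_map
        assert b1.truth == b2.truth
        assert b1.expression.values.equals(b2.expression.values)
        assert nx.utils.graphs_equal(b1.interactome, b2.interactome)

    def test_seeds_differ(self):
        assert not default_bundle(1).expression.values.equals(
            default_bundle(2).expression.values
        )

    def test_planted_hub_recovery_across_seeds(self):
        """The screen's candidates and the planted hubs agree both ways."""
        precisions, recalls = [], []
        for seed in range(10):
            b = default_bundle(seed)
            result = run_screen(b)
            hubs = set(b.truth["planted_hubs"])
            cands = set(result.stage2_nodes)
            assert cands and hubs
            precisions.append(len(cands & hubs) / len(cands))
            recalls.append(len(cands & hubs) / len(hubs))
        assert np.mean(precisions) >= 0.8
        assert np.mean(recalls) >= 0.8


class TestWriteBundle:
    def test_all_files_written_and_readable(self, tmp_path, bundle):
        from netpharm.compounds import read_compound_targets, read_compounds
        from netpharm.deg import read_expression
        from netpharm.enrichment import read_gmt
        from netpharm.network_io import read_edge_list
        import json

        paths = write_bundle(bundle, tmp_path)
        assert read_compounds(paths["compounds"]) == bundle.compounds
        assert read_compound_targets(paths["compound_targets"]) == sorted(
            bundle.compound_target_map
        )
        back = read_edge_list(paths["interactome"])
        assert nx.utils.graphs_equal(back, bundle.interactome)
        expr = read_expression(paths["expression"], bundle.expression.groups)
        assert expr.genes == bundle.expression.genes
        assert read_gmt(paths["genesets"]) == bundle.genesets
        with open(paths["truth"]) as fh:
            assert json.load(fh) == bundle.truth
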