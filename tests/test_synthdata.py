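"""Planted-structure guarantees and determinism of the generator."""

import json

import networkx as nx
import numpy as np
import pytest

from herbnet.adme import AdmeThresholds, ADME_FIELDS, passes_adme, screen_compounds
from herbnet.errors import ConfigError
from herbnet.synthdata import (
    PLANTED_TERM_ID,
    SynthConfig,
    gen_annotations,
    gen_compound_table,
    gen_disease_genes,
    gen_interactome,
    gen_target_map,
    generate_all,
    write_all,
    _rng,
    _target_pool,
)
from herbnet.enrich import hypergeom_p


class TestCompoundTable:
    def test_planted_pass_count_recovered_by_screen(self):
        cfg = SynthConfig(seed=1, n_compounds=100, pass_fraction=0.2, n_whitelisted=5)
        res = screen_compounds(gen_compound_table(cfg))
        assert len(res.adme_passed) == 20
        assert len(res.rescued) == 5

    def test_each_parameter_is_sole_violator_somewhere(self):
        cfg = SynthConfig(seed=3, n_compounds=60, pass_fraction=0.1, n_whitelisted=0,
                          n_targets=20, n_ct_edges=60, interactome_nodes=80,
                          planted_module_size=12, n_disease_genes=10,
                          disease_overlap=0.2, disease_target_overlap=0.2)
        t = AdmeThresholds().as_dict()
        sole = set()
        for c in gen_compound_table(cfg):
            below = [f for f in ADME_FIELDS if getattr(c, f) < t[f]]
            if len(below) == 1:
                sole.add(below[0])
        assert sole == set(ADME_FIELDS)

    def test_determinism_and_seed_sensitivity(self):
        base = dict(n_compounds=50, n_whitelisted=2, n_targets=20, n_ct_edges=60,
                    interactome_nodes=80, planted_module_size=12, n_disease_genes=10,
                    disease_overlap=0.2, disease_target_overlap=0.2)
        cfg = SynthConfig(seed=1, **base)
        assert gen_compound_table(cfg) == gen_compound_table(cfg)
        other = gen_compound_table(SynthConfig(seed=2, **base))
        assert gen_compound_table(cfg) != other

    def test_many_to_many_herb_membership(self):
        table = gen_compound_table(SynthConfig(seed=0, n_compounds=200, n_whitelisted=0))
        assert any(len(c.herbs) > 1 for c in table)

    def test_whitelist_only_on_failing_compounds(self):
        table = gen_compound_table(SynthConfig(seed=5, n_compounds=80, pass_fraction=0.5,
                                               n_whitelisted=10))
        assert all(not passes_adme(c) for c in table if c.whitelisted)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="pass_fraction"):
            SynthConfig(pass_fraction=1.5).validate()
        with pytest.raises(ConfigError, match="n_whitelisted"):
            SynthConfig(n_compounds=10, pass_fraction=1.0, n_whitelisted=1).validate()


class TestInteractome:
    def test_simple_graph_no_self_loops(self, small_config):
        g, _ = gen_interactome(small_config)
        assert not any(u == v for u, v in g.edges())
        assert g.number_of_nodes() == small_config.interactome_nodes

    def test_planted_density_met(self, small_config):
        g, module = gen_interactome(small_config)
        sub = g.subgraph(module)
        s = len(module)
        assert s == small_config.planted_module_size
        assert sub.number_of_edges() / (s * (s - 1) / 2) >= small_config.planted_module_density

    def test_full_density_is_a_clique(self):
        cfg = SynthConfig(seed=2, interactome_nodes=60, planted_module_size=20,
                          planted_module_density=1.0, n_targets=30, n_ct_edges=100,
                          n_disease_genes=30, disease_overlap=0.1, disease_target_overlap=0.2)
        g, module = gen_interactome(cfg)
        assert g.subgraph(module).number_of_edges() == 190  # C(20,2)

    def test_erdos_renyi_p0_without_module_is_edgeless(self):
        cfg = SynthConfig(seed=1, interactome_model="erdos_renyi", er_p=0.0,
                          interactome_nodes=30, planted_module_size=0,
                          n_targets=10, n_ct_edges=30, n_disease_genes=10,
                          disease_overlap=0.0, disease_target_overlap=0.0)
        g, module = gen_interactome(cfg)
        assert g.number_of_edges() == 0 and module == []

    def test_oversized_module_rejected(self):
        with pytest.raises(ConfigError, match="planted_module_size"):
            SynthConfig(interactome_nodes=10, planted_module_size=11).validate()


class TestTargetMapAndDisease:
    def test_exact_edge_and_target_counts(self, small_config):
        data = generate_all(small_config)
        tmap = data["target_map"]
        assert len(set(tmap.table["target_symbol"])) == small_config.n_targets
        assert len(tmap.pairs()) == small_config.n_ct_edges

    def test_targets_are_interactome_proteins(self, small_config):
        data = generate_all(small_config)
        assert set(data["target_map"].table["target_symbol"]) <= set(data["interactome"].nodes())

    def test_disease_overlaps_planted_exactly(self, small_config):
        data = generate_all(small_config)
        disease = set(data["disease_genes"])
        assert len(disease) == small_config.n_disease_genes
        n_mod = round(small_config.disease_overlap * small_config.n_disease_genes)
        n_tgt = round(small_config.disease_target_overlap * small_config.n_disease_genes)
        assert len(disease & set(data["module"])) == n_mod
        assert len(disease & set(data["target_pool"])) == n_tgt

    def test_full_and_zero_module_overlap(self):
        base = dict(n_compounds=50, n_whitelisted=2, n_targets=20, n_ct_edges=60,
                    interactome_nodes=80, planted_module_size=12, n_disease_genes=10,
                    disease_target_overlap=0.0, target_module_overlap=0.0)
        for overlap, expected in ((1.0, 10), (0.0, 0)):
            cfg = SynthConfig(seed=4, disease_overlap=overlap, **base)
            data = generate_all(cfg)
            assert len(set(data["disease_genes"]) & set(data["module"])) == expected

    def test_reproducible_across_calls(self, small_config):
        a = generate_all(small_config)
        b = generate_all(small_config)
        assert a["disease_genes"] == b["disease_genes"]
        assert a["target_map"].pairs() == b["target_map"].pairs()


class TestAnnotations:
    def test_planted_term_has_smallest_p_for_module_query(self, small_config):
        data = generate_all(small_config)
        terms = data["annotations"]
        universe = set(data["interactome"].nodes())
        module = set(data["module"])
        ps = {
            tid: hypergeom_p(len(module & m), len(m), len(module), len(universe))
            for tid, (_, m) in terms.items()
        }
        assert min(ps, key=ps.get) == PLANTED_TERM_ID

    def test_term_sizes_valid_and_within_universe(self, small_config):
        data = generate_all(small_config)
        universe = set(data["interactome"].nodes())
        for _, (_, members) in data["annotations"].items():
            assert 1 <= len(members)
            assert members <= universe

    def test_null_multiplier_gives_uniform_construction(self):
        cfg = SynthConfig(seed=9, n_compounds=50, n_whitelisted=0, n_targets=20,
                          n_ct_edges=60, interactome_nodes=80, planted_module_size=12,
                          n_disease_genes=10, disease_overlap=0.2, disease_target_overlap=0.2,
                          n_terms=10, planted_term_enrichment=1.0)
        g, module = gen_interactome(cfg)
        terms = gen_annotations(cfg, g, module)
        sizes = [len(m) for _, m in terms.values()]
        # no term is constructed preferentially: planted term size is unexceptional
        assert sizes[0] <= max(sizes)


class TestWriteAll:
    def test_byte_identical_rerun(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_all(small_config, d1)
        write_all(small_config, d2)
        for name in ("compounds.tsv", "compound_targets.tsv", "disease_genes.txt",
                     "interactome.sif", "annotations.gmt", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_truth_matches_config(self, small_config, tmp_path):
        write_all(small_config, tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["n_pass"] == small_config.n_pass
        assert truth["n_active"] == small_config.n_active
        assert truth["n_targets"] == small_config.n_targets
        assert truth["planted_term"] == PLANTED_TERM_ID
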