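import math

import numpy as np
import pytest

from netpharm.enrichment import hypergeometric_upper_tail
from netpharm.pipeline import load_input_dir
from netpharm.synthetic import (
    SimulationConfig,
    simulate_all,
    simulate_annotations,
    simulate_formula,
    simulate_ppi,
    write_dataset,
)


def dataset_fingerprint(tmpdir):
    return {
        p.name: p.read_bytes()
        for p in sorted(tmpdir.rglob("*"))
        if p.is_file()
    }


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_targets=120, n_disease_genes=200,
                               compounds_per_herb=15, universe_padding=200,
                               ppi_background_n=80)
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_all(cfg), a)
        write_dataset(simulate_all(cfg), b)
        assert dataset_fingerprint(a) == dataset_fingerprint(b)

    def test_different_seed_differs(self, tmp_path):
        kw = dict(n_targets=120, n_disease_genes=200, compounds_per_herb=15,
                  universe_padding=200, ppi_background_n=80)
        a = simulate_all(SimulationConfig(seed=1, **kw))
        b = simulate_all(SimulationConfig(seed=2, **kw))
        assert a.bipartite.edges != b.bipartite.edges


class TestFormula:
    def test_zero_disease_overlap_empties_intersection(self):
        ds = simulate_formula(SimulationConfig(seed=3, disease_overlap_fraction=0.0))
        assert ds.intersection == set()

    def test_overlap_fraction_controls_intersection_size(self):
        ds = simulate_formula(SimulationConfig(seed=4, disease_overlap_fraction=0.5))
        ratio = len(ds.intersection) / len(ds.formula_targets)
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_pooled_compounds_match_inclusion_exclusion_oracle(self):
        """Sharing scheme: each herb draws k of its cpp compounds from a
        shared pool of size S=cpp, the rest fresh. Inclusion-exclusion gives
        E[pooled] = h*(cpp-k) + S*(1 - ((S-k)/S)^h)."""
        h, cpp, f = 7, 100, 0.2
        k, S = round(f * cpp), cpp
        expected = h * (cpp - k) + S * (1 - ((S - k) / S) ** h)
        counts = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, n_herbs=h, compounds_per_herb=cpp,
                herb_overlap_fraction=f, super_compound=False,
                mean_targets_per_compound=1.0, n_targets=50,
                n_disease_genes=100, disease_overlap_fraction=0.2,
            )
            ds = simulate_formula(cfg)
            counts.append(len(set().union(*ds.herb_map.values())))
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_infeasible_overlap_raises_before_generation(self):
        cfg = SimulationConfig(seed=1, n_disease_genes=10,
                               disease_overlap_fraction=1.0)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_formula(cfg)

    def test_heavy_tail_exponent_concentrates_degree(self):
        flat = simulate_formula(SimulationConfig(seed=5, target_degree_exponent=0.0))
        hubby = simulate_formula(SimulationConfig(seed=5, target_degree_exponent=1.5))

        def top_share(ds):
            degs = sorted(
                (ds.bipartite.target_degree(t) for t in ds.bipartite.targets),
                reverse=True,
            )
            return sum(degs[:10]) / sum(degs)

        assert top_share(hubby) > top_share(flat)


class TestAnnotations:
    def make(self, seed=1, **kw):
        cfg = SimulationConfig(seed=seed, **kw)
        rng = np.random.default_rng(0)
        universe = [f"G{i:04d}" for i in range(2000)]
        inter = set(rng.choice(universe, size=150, replace=False))
        inter |= {nr for nr, _ in cfg.planted_top_nrs}
        universe = sorted(set(universe) | inter)
        return cfg, inter, universe

    def test_term_count_arithmetic(self):
        cfg, inter, universe = self.make()
        sources, _ = simulate_annotations(cfg, inter, universe)
        assert len(sources) == 18  # 6 sources x 3 categories
        assert sum(len(s.terms) for s in sources) == 720

    def test_planted_overlap_tail_probability(self):
        # a 20-gene term drawing 15 from a 30-gene query in a 2000 universe
        assert hypergeometric_upper_tail(2000, 20, 30, 15) < 1e-6

    def test_null_sources_calibrated(self):
        """Without planting, p < 0.001 occurs in at most ~0.1% of terms."""
        hits = total = 0
        for seed in range(50):
            cfg, inter, universe = self.make(seed=seed, planted_enriched_terms=0)
            sources, planted = simulate_annotations(cfg, inter, universe)
            assert all(not v for v in planted.values())
            N = len(universe)
            M = len(set(inter) & set(universe))
            for src in sources:
                for genes in src.terms.values():
                    k = len(genes & inter)
                    p = hypergeometric_upper_tail(N, len(genes), M, k)
                    hits += p < 0.001
                    total += 1
        frac = hits / total
        assert frac <= 0.001 + 3 * math.sqrt(0.001 * 0.999 / total)

    def test_oversized_term_rejected(self):
        cfg = SimulationConfig(seed=1, term_size_range=(30, 60))
        with pytest.raises(ValueError, match="universe"):
            simulate_annotations(cfg, {"A"}, [f"G{i}" for i in range(40)])


class TestPPI:
    def test_single_clique_without_background(self):
        cfg = SimulationConfig(seed=1, ppi_background_p=0.0,
                               planted_complexes=((5, ()),),
                               complex_edge_dropout=0.0)
        ppi, (members,) = simulate_ppi(cfg, [f"G{i}" for i in range(50)])
        assert len(ppi.edges) == 10
        assert len(members) == 5

    def test_two_disjoint_cliques_form_two_components(self):
        import networkx as nx

        cfg = SimulationConfig(seed=2, ppi_background_p=0.0,
                               planted_complexes=((4, ()), (4, ())),
                               complex_edge_dropout=0.0)
        ppi, complexes = simulate_ppi(cfg, [f"G{i}" for i in range(50)])
        g = ppi.to_networkx()
        g.remove_nodes_from(list(nx.isolates(g)))
        comps = sorted(len(c) for c in nx.connected_components(g))
        assert comps == [4, 4]
        assert not (set(complexes[0]) & set(complexes[1]))

    def test_fixed_member_outside_pool_is_error(self):
        cfg = SimulationConfig(seed=1, planted_complexes=((4, ("GHOST",)),))
        with pytest.raises(ValueError, match="GHOST"):
            simulate_ppi(cfg, [f"G{i}" for i in range(50)])

    def test_complex_bigger_than_pool_is_error(self):
        cfg = SimulationConfig(seed=1, planted_complexes=((30, ()),))
        with pytest.raises(ValueError, match="exceeds pool"):
            simulate_ppi(cfg, [f"G{i}" for i in range(10)])


class TestFilesRoundTrip:
    def test_generated_files_pass_loaders_unchanged(self, tmp_path, default_dataset):
        write_dataset(default_dataset, tmp_path)
        data = load_input_dir(tmp_path)
        assert data.bipartite == default_dataset.bipartite
        assert data.disease_genes == default_dataset.disease_genes
        assert sorted(data.nr_catalog) == sorted(default_dataset.nr_catalog)
        assert len(data.sources) == len(default_dataset.sources)
        assert data.ppi.edges == default_dataset.ppi.edges
        loaded_terms = {
            (s.source_name, s.category, t): genes
            for s in data.sources
            for t, genes in s.terms.items()
        }
        original_terms = {
            (s.source_name, s.category, t): genes
            for s in default_dataset.sources
            for t, genes in s.terms.items()
        }
        assert loaded_terms == original_terms
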