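import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpharm.enrichment import (
    EnrichmentCluster,
    EnrichmentTest,
    bh_adjust,
    enrich_source,
    hypergeometric_upper_tail,
    select_top_clusters,
)
from netpharm.model_io import AnnotationSource


def exact_upper_tail(N, K, M, k):
    """Independent oracle: exact rational tail sum with integer binomials."""
    total = Fraction(0)
    for i in range(k, min(K, M) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, M - i), math.comb(N, M))
    return total


class TestHypergeometricUpperTail:
    def test_single_favorable_draw(self):
        assert hypergeometric_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_k_zero_is_one(self):
        assert hypergeometric_upper_tail(100, 10, 20, 0) == 1.0

    def test_against_draw_enumeration(self):
        # literal enumeration of every C(20, 8) query draw
        N, K, M, k = 20, 5, 8, 3
        term = set(range(K))
        hits = sum(
            1
            for draw in itertools.combinations(range(N), M)
            if len(term.intersection(draw)) >= k
        )
        expected = hits / math.comb(N, M)
        assert hypergeometric_upper_tail(N, K, M, k) == pytest.approx(expected, abs=1e-12)

    def test_monotone_non_increasing_in_k(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(1, N + 1))
            M = int(rng.integers(1, N + 1))
            ps = [hypergeometric_upper_tail(N, K, M, k) for k in range(min(K, M) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("args", [(10, 11, 5, 1), (10, 5, 11, 1), (10, 3, 3, 4)])
    def test_bounds_enforced(self, args):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(*args)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        # p*m/rank = (.03, .03, .03); running minimum keeps them all at .03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_longer_hand_computed_vector(self):
        # ranks 1..4: (.004*4/1, .02*4/2, .03*4/3, .05*4/4) = (.016,.04,.04,.05)
        assert bh_adjust([0.004, 0.02, 0.03, 0.05]) == pytest.approx(
            [0.016, 0.04, 0.04, 0.05]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_order_equivariant_and_dominates_p(self, ps):
        adj = bh_adjust(ps)
        rev = bh_adjust(ps[::-1])
        assert adj == pytest.approx(rev[::-1])
        assert all(a >= p - 1e-12 and a <= 1.0 for p, a in zip(ps, adj))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def toy_source():
    terms = {
        "T1": frozenset({"A", "B", "C"}),
        "T2": frozenset({"A", "B", "C", "D", "E", "F"}),
        "T3": frozenset({"G", "H"}),
    }
    universe = frozenset("ABCDEFGHIJKLMNOP")
    return AnnotationSource("toy", "BP", terms, universe)


class TestEnrichSource:
    def test_exact_term_copy_attains_minimal_p(self):
        clusters = enrich_source({"A", "B", "C"}, toy_source())
        best = min(clusters, key=lambda c: c.test.p)
        assert best.term_id == "T1"
        assert best.test.k == 3 and best.members == {"A", "B", "C"}

    def test_query_disjoint_from_all_terms_yields_empty_list(self):
        # N, O, P are in the universe but in no term
        assert enrich_source({"N", "O", "P"}, toy_source()) == []

    def test_out_of_universe_query_genes_dropped_from_m(self):
        clusters = enrich_source({"A", "B", "ZZZ"}, toy_source())
        assert clusters[0].test.M == 2

    def test_fully_out_of_universe_query_is_error(self):
        with pytest.raises(ValueError):
            enrich_source({"ZZZ"}, toy_source())

    def test_planted_synthetic_source_separates(self, default_dataset):
        ds = default_dataset
        query = ds.intersection
        planted = ds.ground_truth["planted_terms"]
        src = ds.sources[0]
        clusters = {c.term_id: c for c in enrich_source(query, src)}
        planted_ids = planted[f"{src.source_name}.{src.category}"]
        for term_id in planted_ids:
            assert clusters[term_id].test.p_adj < 0.05
        background_sig = [
            c
            for tid, c in clusters.items()
            if tid not in planted_ids and c.test.p_adj < 0.05
        ]
        assert len(background_sig) < len(planted_ids)


def make_cluster(source, category, term_id, p):
    return EnrichmentCluster(
        term_id, source, category, frozenset({"G"}),
        EnrichmentTest(100, 10, 10, 1, p, min(1.0, p * 2)),
    )


class TestSelectTopClusters:
    def test_saturated_groups_give_sources_times_categories_times_k(self):
        clusters = [
            make_cluster(f"db{s}", cat, f"t{i:03d}", 0.001 + i * 1e-5)
            for s in range(6)
            for cat in ("BP", "MF", "CC")
            for i in range(40)
        ]
        assert len(select_top_clusters(clusters, top_k=30, alpha=0.05)) == 540

    def test_unsaturated_group_contributes_all_significant(self):
        clusters = [make_cluster("db1", "BP", f"t{i}", 0.01) for i in range(12)]
        clusters += [make_cluster("db1", "BP", f"u{i}", 0.9) for i in range(30)]
        assert len(select_top_clusters(clusters)) == 12

    def test_tie_at_cutoff_broken_by_term_id(self):
        clusters = [make_cluster("db1", "BP", f"t{i:03d}", 0.001) for i in range(29)]
        clusters += [
            make_cluster("db1", "BP", "tie_a", 0.02),
            make_cluster("db1", "BP", "tie_b", 0.02),
        ]
        selected = select_top_clusters(clusters, top_k=30)
        ids = {c.term_id for c in selected}
        assert "tie_a" in ids and "tie_b" not in ids

    def test_never_exceeds_groups_times_k(self):
        clusters = [
            make_cluster("db1", cat, f"t{i}", 0.001)
            for cat in ("BP", "MF")
            for i in range(50)
        ]
        assert len(select_top_clusters(clusters, top_k=30)) == 60


class TestNullCalibration:
    def test_type_one_error_valid_and_nonvacuous(self):
        """On null (unplanted) sources the achieved size P(p < 0.05) must not
        exceed the nominal level (hypergeometric p-values are discrete, hence
        conservative) while remaining clearly nonzero."""
        rng = np.random.default_rng(11)
        universe = [f"G{i:04d}" for i in range(2000)]
        n_terms, n_seeds = 40, 200
        hits = total = 0
        for _ in range(n_seeds):
            query = set(rng.choice(universe, size=150, replace=False))
            terms = {
                f"t{i}": frozenset(
                    rng.choice(universe, size=int(rng.integers(15, 26)), replace=False)
                )
                for i in range(n_terms)
            }
            N, M = 2000, 150
            for genes in terms.values():
                k = len(genes & query)
                p = hypergeometric_upper_tail(N, len(genes), M, k)
                hits += p < 0.05
                total += 1
        frac = hits / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert frac <= 0.05 + 3 * se
        assert frac > 0.005
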