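import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import exact_hypergeom_cdf, exact_hypergeom_sf
from postdauer.genesets import (GeneSet, dependence_partition, enrichment_test,
                                jaccard_percent, log_hypergeom_cdf,
                                log_hypergeom_sf, overlap, p_display,
                                percent_of_query, read_gene_list,
                                write_gene_list, _log_pmf_terms)


def gs(name, *members):
    return GeneSet(name, frozenset(members))


class TestOverlapAndPercentages:
    def test_overlap_partitions(self):
        assert overlap(gs("a", "x", "y", "z"), gs("b", "y", "z", "w")) == (2, 1, 1)
        assert overlap(gs("a", "x"), gs("b", "y")) == (0, 1, 1)
        a = gs("a", "x", "y")
        assert overlap(a, a) == (2, 0, 0)

    @pytest.mark.parametrize("k,n,dec,expect", [
        # printed transcriptome-comparison percentages
        (3652, 5908, 0, 62),    # CeNGEN vs control
        (4779, 5908, 0, 81),    # pan-neuronal vs control
        (175, 711, 1, 24.6),    # DE genes previously seen in neurons
        (308, 711, 0, 43),      # DE genes germline-expressed
        (33, 101, 1, 32.7),     # secreted-protein fraction of dependent-up
        (81, 542, 1, 14.9),     # collagen fraction of dependent-down
        (0, 10, 1, 0.0),
    ])
    def test_percent_of_query_reproduces_printed_figures(self, k, n, dec, expect):
        assert percent_of_query(k, n, dec) == expect

    def test_percent_errors(self):
        with pytest.raises(ValueError):
            percent_of_query(1, 0)
        with pytest.raises(ValueError):
            percent_of_query(5, 4)

    def test_half_away_from_zero_rounding(self):
        assert percent_of_query(1, 8, 1) == 12.5
        assert percent_of_query(1, 8, 0) == 13  # 12.5 rounds away from zero

    @pytest.mark.parametrize("a,b,k,expect", [
        (5908, 6001, 5206, 77.7),  # wild-type vs nrde-3 control transcriptomes
        (6375, 6377, 5951, 87.5),  # wild-type vs nrde-3 post-dauer
        (7, 7, 7, 100.0),
    ])
    def test_jaccard_reproduces_printed_similarities(self, a, b, k, expect):
        assert jaccard_percent(a, b, k, 1) == expect

    def test_jaccard_bounded_by_query_percents(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.integers(1, 1000, size=2)
            k = int(rng.integers(0, min(a, b) + 1))
            j = jaccard_percent(int(a), int(b), k, 6)
            assert j <= min(percent_of_query(k, int(a), 6),
                            percent_of_query(k, int(b), 6)) + 1e-9

    def test_jaccard_degenerate_union(self):
        with pytest.raises(ValueError):
            jaccard_percent(0, 0, 0)


class TestLogHypergeom:
    def test_certain_event(self):
        assert log_hypergeom_sf(0, 5, 5, 10) == 0.0

    def test_single_subset_case(self):
        # only one 5-subset of the 5 reference members among C(10,5)=252
        assert log_hypergeom_sf(5, 5, 5, 10) == pytest.approx(
            math.log10(Fraction(1, 252)), abs=1e-12)

    def test_small_enumeration_case(self):
        # P = (C(3,2)C(3,1)+C(3,3)C(3,0))/C(6,3) = 10/20
        assert log_hypergeom_sf(2, 3, 3, 6) == pytest.approx(
            math.log10(0.5), abs=1e-12)

    def test_full_grid_matches_exact_rationals_up_to_N25(self):
        for N in range(1, 26):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        exact = exact_hypergeom_sf(k, n, K, N)
                        got = log_hypergeom_sf(k, n, K, N)
                        want = math.log10(exact)
                        assert got == pytest.approx(want, abs=1e-10), (k, n, K, N)

    @pytest.mark.parametrize("N,n,K", [(100, 30, 40), (10_000, 900, 2500)])
    def test_pmf_normalizes_in_log_space(self, N, n, K):
        lo, hi = max(0, n + K - N), min(n, K)
        total = math.fsum(10.0 ** t for t in _log_pmf_terms(n, K, N, lo, hi))
        assert abs(total - 1.0) < 1e-12

    def test_monotone_nonincreasing_in_k(self):
        vals = [log_hypergeom_sf(k, 50, 60, 200) for k in range(0, 51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_symmetry_in_query_and_reference(self):
        for k in (0, 5, 17, 30):
            assert log_hypergeom_sf(k, 30, 80, 500) == pytest.approx(
                log_hypergeom_sf(k, 80, 30, 500), rel=1e-12)

    def test_extreme_tail_against_mpmath(self):
        # magnitudes around 1e-1200, far below double-precision underflow
        import mpmath

        mpmath.mp.dps = 60
        for k, n, K, N in [(4779, 5908, 8436, 20000),
                           (5951, 6375, 6377, 20000)]:
            acc = mpmath.mpf(0)
            for i in range(k, min(n, K) + 1):
                acc += (mpmath.binomial(K, i) * mpmath.binomial(N - K, n - i)
                        / mpmath.binomial(N, n))
            want = float(mpmath.log10(acc))
            got = log_hypergeom_sf(k, n, K, N)
            assert got == pytest.approx(want, abs=1e-8)
            assert math.isfinite(got) and got < -1000

    @pytest.mark.parametrize("printed,k,n,K,N,tail", [
        # printed p-values reproduce exactly with a 20000-gene population
        ("1.26e-514", 3652, 5908, 7217, 20000, "upper"),
        ("6.30e-719", 4129, 6375, 7217, 20000, "upper"),
        ("9.75e-1161", 4779, 5908, 8436, 20000, "upper"),
        ("3.71e-1396", 5240, 6375, 8436, 20000, "upper"),
        ("5.17e-3045", 5206, 5908, 6001, 20000, "upper"),
        ("4.07e-3939", 5951, 6375, 6377, 20000, "upper"),
    ])
    def test_printed_pvalues_reproduce_at_population_20000(
            self, printed, k, n, K, N, tail):
        assert p_display(log_hypergeom_sf(k, n, K, N)) == printed

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            log_hypergeom_sf(5, 3, 3, 6)
        with pytest.raises(ValueError):
            log_hypergeom_sf(1, 7, 3, 6)

    def test_lower_tail_matches_exact(self):
        for k, n, K, N in [(0, 3, 3, 9), (2, 5, 4, 12), (3, 6, 6, 12)]:
            assert log_hypergeom_cdf(k, n, K, N) == pytest.approx(
                math.log10(exact_hypergeom_cdf(k, n, K, N)), abs=1e-10)


class TestPDisplay:
    def test_renders_without_exponentiating(self):
        assert p_display(-1160.0111516) == "9.75e-1161"
        assert p_display(0.0) == "1"

    def test_mantissa_carry(self):
        # log10_p just below an integer: mantissa 9.999 -> 10.0 carries
        assert p_display(-513.0000001) == "1.00e-513"


class TestEnrichmentTest:
    def test_reference_equals_population_saturates(self):
        pop = gs("pop", *[f"g{i}" for i in range(20)])
        q = gs("q", "g1", "g2", "g3")
        r = enrichment_test(q, pop, pop)
        assert r.fold == pytest.approx(1.0)
        assert r.log10_p == 0.0
        assert r.direction == "enriched"

    def test_boundary_k_equals_expected(self):
        pop = gs("pop", *[f"g{i}" for i in range(10)])
        q = gs("q", "g0", "g1", "g2", "g3", "g4")
        ref = gs("r", "g0", "g1", "g5", "g6")  # expected = 5*4/10 = 2 = k
        r = enrichment_test(q, ref, pop)
        assert (r.k, r.direction, r.fold) == (2, "enriched", pytest.approx(1.0))

    def test_membership_violation_lists_offenders(self):
        pop = gs("pop", "g1", "g2")
        with pytest.raises(ValueError, match="gX"):
            enrichment_test(gs("q", "g1", "gX"), gs("r", "g2"), pop)

    def test_depleted_uses_lower_tail_and_inverse_fold(self):
        pop = gs("pop", *[f"g{i}" for i in range(100)])
        q = gs("q", *[f"g{i}" for i in range(50)])
        ref = gs("r", *[f"g{i}" for i in range(48, 98)])  # k=2, expected=25
        r = enrichment_test(q, ref, pop)
        assert r.direction == "depleted"
        assert r.fold == pytest.approx(25 / 2)
        assert r.log10_p == pytest.approx(
            math.log10(exact_hypergeom_cdf(2, 50, 50, 100)), abs=1e-9)


class TestDependencePartition:
    def _sets(self, wt_up_n=116, shared_up=15, mut_up_n=96,
              wt_down_n=595, shared_down=53, mut_down_n=105):
        wt_up = {f"u{i}" for i in range(wt_up_n)}
        mut_up = {f"u{i}" for i in range(shared_up)} | \
                 {f"mu{i}" for i in range(mut_up_n - shared_up)}
        wt_down = {f"d{i}" for i in range(wt_down_n)}
        mut_down = {f"d{i}" for i in range(shared_down)} | \
                   {f"md{i}" for i in range(mut_down_n - shared_down)}
        return (GeneSet("wt_up", wt_up), GeneSet("wt_down", wt_down),
                GeneSet("mut_up", mut_up), GeneSet("mut_down", mut_down))

    def test_reproduces_printed_dependence_counts(self):
        # 116 wild-type up with 15 shared -> 101 dependent; 595 down with
        # 53 shared -> 542 dependent; (101+542)/711 -> 90%
        part = dependence_partition(*self._sets())
        assert len(part.dependent_up) == 101
        assert len(part.dependent_down) == 542
        assert part.percent_dependent == 90

    def test_up_down_overlap_within_genotype_rejected(self):
        both = GeneSet("x", frozenset({"g"}))
        with pytest.raises(ValueError):
            dependence_partition(both, both, GeneSet("a", frozenset()),
                                 GeneSet("b", frozenset()))

    def test_invariant_under_relabeling(self):
        part1 = dependence_partition(*self._sets())
        relabeled = [GeneSet(s.name, frozenset("X" + m for m in s.members))
                     for s in self._sets()]
        part2 = dependence_partition(*relabeled)
        assert (len(part1.dependent_up), len(part1.dependent_down),
                part1.shared_up, part1.shared_down) == \
               (len(part2.dependent_up), len(part2.dependent_down),
                part2.shared_up, part2.shared_down)


def test_gene_list_round_trip(tmp_path):
    g = gs("mylist", "b", "a", "c")
    p = tmp_path / "list.txt"
    write_gene_list(g, p)
    p.write_text(p.read_text() + "# comment line\n a # trailing\n")
    back = read_gene_list(p, "mylist")
    assert back.members == g.members


@given(st.sets(st.text("abcdef", min_size=1, max_size=3), max_size=20),
       st.sets(st.text("abcdef", min_size=1, max_size=3), max_size=20))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_overlap_partition_sums_to_union(a, b):
    k, only_a, only_b = overlap(GeneSet("a", frozenset(a)) if a else gs("a"),
                                GeneSet("b", frozenset(b)) if b else gs("b"))
    assert k + only_a + only_b == len(a | b)
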