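"""Subfamily clustering and enrichment statistics against independent oracles."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from plasmidkit import protfam, synth
from plasmidkit.protfam import ProteinRecord


def _random_protein(pid, n, seed, source_class="reference"):
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, n)])
    return ProteinRecord(pid, "g", source_class, seq)


def fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher oracle: exact rationals, direct table
    enumeration via the factorial formula, same tie rule (1 + 1e-7)."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if n == 0:
        return Fraction(1)

    def pmf(x):
        bb, cc, dd = r1 - x, c1 - x, r2 - (c1 - x)
        if min(bb, cc, dd) < 0:
            return None
        num = (
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(c2)
        )
        den = (
            math.factorial(n) * math.factorial(x) * math.factorial(bb)
            * math.factorial(cc) * math.factorial(dd)
        )
        return Fraction(num, den)

    observed = pmf(a)
    tol = Fraction(10**7 + 1, 10**7)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = pmf(x)
        if p is not None and p <= observed * tol:
            total += p
    return min(Fraction(1), total)


class TestFisher:
    def test_diagonal_table_is_one_third(self):
        # margins (2,2)/(2,2): 6 tables, the two diagonal ones weigh 1 each
        assert protfam.fisher_two_sided(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_flat_table_is_one(self):
        assert protfam.fisher_two_sided(1, 1, 1, 1) == pytest.approx(1.0)

    def test_all_zero_margins(self):
        assert protfam.fisher_two_sided(0, 0, 0, 0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            protfam.fisher_two_sided(-1, 0, 0, 0)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_big_integer_oracle(self, a, b, c, d):
        ours = protfam.fisher_two_sided(a, b, c, d)
        assert ours == pytest.approx(float(fisher_oracle(a, b, c, d)), rel=1e-12)

    def test_matches_scipy_on_a_grid(self):
        from scipy.stats import fisher_exact

        for a, b, c, d in [(3, 0, 27, 200), (5, 5, 10, 80), (2, 8, 20, 70),
                           (0, 10, 10, 0), (7, 1, 2, 9)]:
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert protfam.fisher_two_sided(a, b, c, d) == pytest.approx(p, rel=1e-9)


class TestBH:
    def test_step_up_examples(self):
        assert protfam.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert protfam.bh_fdr([0.05, 0.01]) == pytest.approx([0.05, 0.02])
        assert protfam.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            protfam.bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_statsmodels_and_is_permutation_invariant(self, pvals):
        ours = protfam.bh_fdr(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert ours == pytest.approx(list(ref), rel=1e-12, abs=1e-12)
        perm = list(reversed(pvals))
        assert sorted(protfam.bh_fdr(perm)) == pytest.approx(sorted(ours))

    def test_monotone_in_sorted_order(self):
        pvals = [0.04, 0.001, 0.3, 0.02, 0.9]
        q = protfam.bh_fdr(pvals)
        order = np.argsort(pvals)
        assert all(
            q[order[i]] <= q[order[i + 1]] + 1e-15 for i in range(len(q) - 1)
        )


class TestPercentEnrichment:
    @pytest.mark.parametrize(
        "n_plasmid,n_total,expected", [(3, 13, 23), (3, 4, 75), (2, 2, 100),
                                       (3, 7, 43), (8, 65, 12)]
    )
    def test_published_style_cells(self, n_plasmid, n_total, expected):
        assert protfam.percent_enrichment(n_plasmid, n_total) == expected

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            protfam.percent_enrichment(1, 0)
        with pytest.raises(ValueError):
            protfam.percent_enrichment(5, 4)


class TestPairwiseSimilarity:
    def test_identical_proteins_edge_with_full_coverage(self):
        p1 = _random_protein("a", 200, 1)
        p2 = ProteinRecord("b", "g", "reference", p1.sequence)
        edge = protfam.pairwise_similarity(p1, p2, db_size=40_000)
        assert edge is not None
        assert edge.coverage == pytest.approx(1.0)
        assert edge.evalue < 1e-10

    def test_random_pair_no_edge(self):
        p1 = _random_protein("a", 200, 2)
        p2 = _random_protein("b", 200, 3)
        assert protfam.pairwise_similarity(p1, p2, db_size=40_000) is None

    def test_short_shared_segment_fails_coverage(self):
        rng_a = _random_protein("a", 200, 4)
        seq_b = list(_random_protein("x", 200, 5).sequence)
        seq_b[75:125] = rng_a.sequence[75:125]
        p2 = ProteinRecord("b", "g", "reference", "".join(seq_b))
        assert protfam.pairwise_similarity(rng_a, p2, db_size=40_000) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("a", "g", "reference", "")

    def test_null_calibration_no_edges_among_random_proteins(self):
        prots = [_random_protein(f"p{i:02d}", 200, 100 + i) for i in range(16)]
        assert protfam.all_vs_all(prots) == []

    def test_symmetry_and_determinism(self):
        p1 = _random_protein("a", 150, 6)
        p2 = ProteinRecord("b", "g", "reference", p1.sequence)
        e1 = protfam.pairwise_similarity(p1, p2, db_size=300)
        e2 = protfam.pairwise_similarity(p2, p1, db_size=300)
        assert (e1.query_id, e1.target_id) == (e2.query_id, e2.target_id) == ("a", "b")
        assert e1.score == e2.score


class TestAllVsAll:
    def test_planted_family_fully_connected(self):
        prots, _ = synth.generate_protein_universe(
            n_families=1, family_size_dist=[5], substitution_rate=0.1,
            n_background=0, rng_seed=7,
        )
        edges = protfam.all_vs_all(prots)
        assert len(edges) == 10  # all C(5,2) pairs

    def test_kmer_prefilter_keeps_family_edges(self):
        prots, _ = synth.generate_protein_universe(
            n_families=2, family_size_dist=[4, 4], substitution_rate=0.1,
            n_background=10, rng_seed=8,
        )
        full = protfam.all_vs_all(prots)
        filtered = protfam.all_vs_all(prots, kmer_prefilter=6)
        assert {(e.query_id, e.target_id) for e in filtered} == {
            (e.query_id, e.target_id) for e in full
        }


class TestGreedySetCover:
    def test_no_edges_all_singletons(self):
        prots = [_random_protein(f"p{i}", 50, i) for i in range(4)]
        subs = protfam.greedy_set_cover_cluster(prots, [])
        assert len(subs) == 4 and all(s.size == 1 for s in subs)

    def test_clique_of_five_one_subfamily(self):
        prots = [_random_protein(f"p{i}", 50, i) for i in range(5)]
        edges = [
            protfam.SimilarityEdge(*sorted((a.id, b.id)), 100, 30, 1e-9, 1.0)
            for a, b in combinations(prots, 2)
        ]
        subs = protfam.greedy_set_cover_cluster(prots, edges)
        assert len(subs) == 1 and subs[0].size == 5

    def test_path_centre_becomes_representative(self):
        # brute-force minimum set cover of a--b--c is {N[b]}: one subfamily
        prots = [_random_protein(x, 50, i) for i, x in enumerate("abc")]
        edges = [
            protfam.SimilarityEdge("a", "b", 100, 30, 1e-9, 1.0),
            protfam.SimilarityEdge("b", "c", 100, 30, 1e-9, 1.0),
        ]
        subs = protfam.greedy_set_cover_cluster(prots, edges)
        assert len(subs) == 1
        assert subs[0].representative_id == "b"
        assert subs[0].member_ids == ("a", "b", "c")

    def test_partition_property(self):
        prots, _ = synth.generate_protein_universe(
            n_families=6, substitution_rate=0.05, n_background=15, rng_seed=9
        )
        edges = protfam.all_vs_all(prots, kmer_prefilter=6)
        subs = protfam.greedy_set_cover_cluster(prots, edges)
        members = [m for s in subs for m in s.member_ids]
        assert sorted(members) == sorted(p.id for p in prots)


class TestEnrichment:
    def _subfam(self, sid, members):
        return protfam.Subfamily(sid, members[0], tuple(members))

    def test_planted_plasmid_only_family_enriched(self):
        labels = {}
        subs = []
        for i in range(3):  # three plasmid-only families of 4
            members = [f"pl{i}_{j}" for j in range(4)]
            subs.append(self._subfam(f"sf{i}", members))
            labels.update({m: "plasmid" for m in members})
        for i in range(20):  # background: host-only families of 4
            members = [f"ho{i}_{j}" for j in range(4)]
            subs.append(self._subfam(f"sh{i}", members))
            labels.update({m: "reference" for m in members})
        results = protfam.enriched_subfamilies(subs, labels)
        by_id = {r.subfamily_id: r for r in results}
        for i in range(3):
            r = by_id[f"sf{i}"]
            assert r.enriched and r.odds_ratio == math.inf
            assert r.percent_enrichment == 100
        assert not any(by_id[f"sh{i}"].enriched for i in range(20))

    def test_background_rate_family_not_enriched(self):
        # family plasmid fraction equals the universe's: Fisher p ~ 1
        labels = {}
        subs = []
        for i in range(10):
            members = [f"f{i}_{j}" for j in range(4)]
            subs.append(self._subfam(f"sf{i}", members))
            for j, m in enumerate(members):
                labels[m] = "plasmid" if j < 2 else "reference"
        results = protfam.enriched_subfamilies(subs, labels)
        assert not any(r.enriched for r in results)
        assert all(r.p == pytest.approx(1.0) for r in results)

    def test_singletons_clustered_but_not_tested(self):
        subs = [
            self._subfam("s0", ["a", "b"]),
            self._subfam("s1", ["c"]),
        ]
        labels = {"a": "plasmid", "b": "plasmid", "c": "reference"}
        results = protfam.enriched_subfamilies(subs, labels)
        assert [r.subfamily_id for r in results] == ["s0"]

    def test_unlabeled_protein_rejected(self):
        subs = [self._subfam("s0", ["a", "b"])]
        with pytest.raises(ValueError):
            protfam.enriched_subfamilies(subs, {"a": "plasmid"})


class TestPairF1:
    def test_perfect_recovery_is_one(self):
        truth = {"a": "f1", "b": "f1", "c": "f2", "d": "f2"}
        subs = [
            protfam.Subfamily("s0", "a", ("a", "b")),
            protfam.Subfamily("s1", "c", ("c", "d")),
        ]
        assert protfam.pair_f1(truth, subs) == 1.0

    def test_merged_clusters_lose_precision(self):
        truth = {"a": "f1", "b": "f1", "c": "f2", "d": "f2"}
        subs = [protfam.Subfamily("s0", "a", ("a", "b", "c", "d"))]
        f1 = protfam.pair_f1(truth, subs)
        assert f1 == pytest.approx(2 * (2 / 6) * 1.0 / ((2 / 6) + 1.0))
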