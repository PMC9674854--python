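"""Generator checks: the planted signals match their analytic expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidkit import circ, skew, synth
from plasmidkit.discover import GeneFeature
from plasmidkit.hostlink import coverage_from_alignments


class TestReplichoreSequence:
    @pytest.mark.parametrize(
        "a,leading,expected",
        [(0.0, True, 0.0), (0.1, True, 0.1), (0.1, False, -0.1)],
    )
    def test_mean_window_skew_matches_amplitude(self, a, leading, expected):
        seq = synth.generate_replichore_sequence(100_000, 0.4, a, leading, 1)
        profile = skew.windowed_skew(seq, 1000, 1000, circular=False)
        assert abs(profile.skew.mean() - expected) < 0.02

    def test_full_amplitude_leading_has_no_c(self):
        seq = synth.generate_replichore_sequence(5000, 0.4, 0.999999, True, 2)
        assert seq.count("C") == 0 or seq.count("C") < 2  # P(C) ~ 1e-7

    def test_gc_content_matches_request(self):
        seq = synth.generate_replichore_sequence(100_000, 0.4, 0.1, True, 3)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.4) < 0.01

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_replichore_sequence(100, 1.2, 0.1)
        with pytest.raises(ValueError):
            synth.generate_replichore_sequence(100, 0.4, 1.0)


class TestGeneratePlasmid:
    def test_cumulative_skew_minimum_at_planted_origin(self):
        spec = synth.CommunitySpec(seed=4, plasmid_length=100_000, origin_pos=0)
        seq, truth = synth.generate_plasmid(spec)
        profile = skew.windowed_skew(seq, 1000, 1000, circular=True)
        origin, _, _ = skew.predict_origin_terminus(profile)
        err = min(origin, spec.plasmid_length - origin)
        assert err <= 2 * 1000

    def test_at_rich_dip_present_and_absent(self):
        base = dict(seed=5, plasmid_length=60_000, skew_amplitude=0.0)
        with_dip = synth.CommunitySpec(**base, at_rich_origin_len=2000)
        without = synth.CommunitySpec(**base, at_rich_origin_len=0)
        seq1, _ = synth.generate_plasmid(with_dip)
        seq0, _ = synth.generate_plasmid(without)

        def gc_of(s):
            return (s.count("G") + s.count("C")) / len(s)

        assert gc_of(seq1[:2000]) < gc_of(seq1[2000:]) - 0.1
        assert abs(gc_of(seq0[:2000]) - gc_of(seq0[2000:])) < 0.05

    def test_terminus_is_half_way_round(self):
        spec = synth.CommunitySpec(seed=6, origin_pos=40_000)
        _, truth = synth.generate_plasmid(spec)
        expected = (40_000 + spec.plasmid_length // 2) % spec.plasmid_length
        assert truth.true_terminus == expected


class TestLinearize:
    def test_construction_example(self):
        assert synth.linearize_with_overlap("ACGTACGT", 0, 3) == "ACGTACGTACG"

    def test_zero_overlap_is_plain_rotation(self):
        assert synth.linearize_with_overlap("ACGTACGT", 2, 0) == "GTACGTAC"

    def test_overlap_too_long_rejected(self):
        with pytest.raises(ValueError):
            synth.linearize_with_overlap("ACGT", 0, 4)

    @settings(max_examples=50, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=60, max_size=300),
        frac_break=st.floats(0, 0.999),
        overlap=st.integers(0, 50),
    )
    def test_trim_round_trip_recovers_rotation(self, seq, frac_break, overlap):
        if overlap >= len(seq):
            overlap = len(seq) - 1
        b = int(frac_break * len(seq))
        linear = synth.linearize_with_overlap(seq, b, overlap)
        back = circ.trim_and_circularize(linear, overlap)
        assert back == seq[b:] + seq[:b]
        assert len(back) == len(seq)


class TestSimulatedAlignments:
    def test_pair_count_and_coverage_match_requested_depth(self):
        reps = [synth.RepliconSpec("r", 100_000, circular=False)]
        recs = synth.simulate_paired_alignments(
            reps, {"r": 20.0}, read_length=100, insert_mean=300, insert_sd=30,
            rng_seed=7,
        )
        n_pairs = len(recs) // 2
        assert abs(n_pairs - 10_000) <= 1000
        cov = coverage_from_alignments(recs, "r", 100_000)
        assert 18.0 <= cov <= 22.0

    def test_equal_depths_give_unit_coverage_ratio(self):
        reps = [
            synth.RepliconSpec("a", 50_000, circular=False),
            synth.RepliconSpec("b", 50_000, circular=True),
        ]
        recs = synth.simulate_paired_alignments(
            reps, {"a": 20.0, "b": 20.0}, 100, 300, 30, rng_seed=8
        )
        ratio = coverage_from_alignments(recs, "b", 50_000) / coverage_from_alignments(
            recs, "a", 50_000
        )
        assert 0.9 <= ratio <= 1.1

    def test_zero_depth_gives_zero_records(self):
        reps = [synth.RepliconSpec("r", 10_000)]
        assert synth.simulate_paired_alignments(reps, {"r": 0.0}, rng_seed=9) == []

    def test_insert_shorter_than_read_rejected(self):
        reps = [synth.RepliconSpec("r", 10_000)]
        with pytest.raises(ValueError):
            synth.simulate_paired_alignments(
                reps, {"r": 1.0}, read_length=150, insert_mean=100
            )


class TestSimulatedExpression:
    def _genes(self, n, length=2000):
        return [
            GeneFeature(f"g{i:03d}", "c", i * (length + 50), i * (length + 50) + length)
            for i in range(n)
        ]

    def test_zero_rate_genes_get_zero_reads(self):
        genes = self._genes(5)
        recs = synth.simulate_expression(genes, {g.id: 0.0 for g in genes}, rng_seed=1)
        assert recs == []

    def test_poisson_mean_rate5_len2000_is_10(self):
        genes = self._genes(300)
        recs = synth.simulate_expression(genes, {g.id: 5.0 for g in genes}, rng_seed=2)
        mean_count = len(recs) / len(genes)
        assert abs(mean_count - 10.0) < 0.6  # 3 sigma ~ 0.55

    def test_total_counts_near_sum_of_means(self):
        genes = self._genes(100)
        rates = {g.id: float(i % 7) for i, g in enumerate(genes)}
        recs = synth.simulate_expression(genes, rates, rng_seed=3)
        expected = sum(r * 2000 / 1000 for r in rates.values())
        assert abs(len(recs) - expected) < 4 * np.sqrt(expected)

    def test_reads_fall_inside_their_gene(self):
        genes = self._genes(3)
        recs = synth.simulate_expression(genes, {g.id: 20.0 for g in genes}, rng_seed=4)
        spans = {g.id: (g.start, g.end) for g in genes}
        for r in recs:
            gid = r.read_id.split(":")[0]
            assert spans[gid][0] <= r.start and r.end <= spans[gid][1]


class TestProteinUniverse:
    @staticmethod
    def _identity(s1, s2):
        return sum(a == b for a, b in zip(s1, s2)) / len(s1)

    def test_zero_rate_families_are_identical(self):
        prots, _ = synth.generate_protein_universe(
            n_families=3, family_size_dist=[3, 3, 3], substitution_rate=0.0,
            n_background=0, rng_seed=1,
        )
        fams = {}
        for p in prots:
            fams.setdefault(p.id.split(".")[0], []).append(p.sequence)
        for seqs in fams.values():
            assert len(set(seqs)) == 1

    def test_within_and_between_family_identity(self):
        # pairwise identity per site: (1-p)^2 + p^2/19 ~ 0.8105 at p = 0.1
        prots, truth = synth.generate_protein_universe(
            n_families=10, substitution_rate=0.1, n_background=0, rng_seed=2
        )
        fam = truth.true_family_of_protein
        within, between = [], []
        for i, p in enumerate(prots):
            for q in prots[i + 1 :]:
                ident = self._identity(p.sequence, q.sequence)
                (within if fam[p.id] == fam[q.id] else between).append(ident)
        assert 0.75 < np.mean(within) < 0.87
        assert np.mean(between) < 0.10

    def test_ids_carry_source_labels(self):
        prots, _ = synth.generate_protein_universe(
            n_families=4, family_size_dist=[2, 2, 2, 2],
            source_assignment={0: "plasmid", 1: "both", 2: "host", 3: "host"},
            n_background=2, rng_seed=3,
        )
        for p in prots:
            label = p.id.rsplit("_", 1)[1]
            assert label in ("plasmid", "host", "reference")
            if label == "plasmid":
                assert p.source_class == "plasmid"


class TestDeterminism:
    def test_same_spec_same_seed_reproduces_everything(self, small_spec):
        c1 = synth.generate_community(small_spec)
        c2 = synth.generate_community(small_spec)
        assert c1.contigs[0].sequence == c2.contigs[0].sequence
        assert c1.genome_alignments == c2.genome_alignments
        assert c1.transcript_alignments == c2.transcript_alignments
        assert c1.expression_rates == c2.expression_rates
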