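import numpy as np
import pytest

from tigrkit import (
    NucSeq,
    GuidePair,
    MismatchModel,
    find_sites,
    brute_force_find_sites,
    predict_cleavage,
    gap_scan,
    ssdna_scan,
    off_target_scan,
    self_target_check,
    build_expression_array,
)
from tigrkit.fixtures import TA_LIKE_REPEAT_SET, make_target_genome
from tigrkit.seq import revcomp_str, rna_to_dna_str, dna_to_rna_str


class TestGuidePair:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            GuidePair("ACGUACG", "GGAUCCGGA")

    def test_rna_alphabet_required(self):
        with pytest.raises(ValueError):
            GuidePair("ACGTACGTA", "GGAUCCGGA")


class TestFindSites:
    def test_worked_example(self, example_genome, example_guide):
        sites = find_sites(example_genome, example_guide)
        assert len(sites) == 1
        site = sites[0]
        assert (site.start, site.end) == (100, 118)
        assert site.gap == 0
        # spacer A pairs the bottom strand over the left 9 bp
        assert site.region_a == (100, 109, "-")
        assert site.region_b == (109, 118, "+")
        assert site.mismatches_a == [] and site.mismatches_b == []

    def test_reverse_complemented_spacer_not_functional(self, example_genome, example_guide):
        rc_b = dna_to_rna_str(revcomp_str(rna_to_dna_str(example_guide.spacer_b)))
        assert find_sites(example_genome, GuidePair(example_guide.spacer_a, rc_b)) == []

    def test_spacer_swap_finds_same_site(self, example_genome, example_guide):
        swapped = example_guide.swapped()
        sites = find_sites(example_genome, swapped)
        assert [(s.start, s.end, s.gap) for s in sites] == [(100, 118, 0)]
        # geometry is preserved, region labels swap
        assert sites[0].region_b == (100, 109, "-")
        assert sites[0].region_a == (109, 118, "+")

    def test_revcomp_invariance(self, example_genome, example_guide):
        sites = find_sites(example_genome, example_guide)
        rc = NucSeq("rc", revcomp_str(example_genome.seq))
        mirrored = find_sites(rc, example_guide)
        L = len(example_genome)
        assert {(L - s.end, L - s.start) for s in mirrored} == {
            (s.start, s.end) for s in sites
        }

    def test_flank_randomization_invariance(self, example_genome, example_guide):
        site = find_sites(example_genome, example_guide)[0]
        rng = np.random.default_rng(55)
        s = list(example_genome.seq)
        for i in range(len(s)):
            if not (site.start <= i < site.end):
                s[i] = "ACGT"[rng.integers(4)]
        shuffled = NucSeq("shuffled", "".join(s))
        again = find_sites(shuffled, example_guide)
        assert [(x.start, x.end, x.gap) for x in again] == [(100, 118, 0)]
        assert predict_cleavage(again[0]).outcome == "dsb"


class TestBruteForceOracle:
    def test_equivalence_on_fixed_genome(self, example_genome, example_guide):
        assert find_sites(example_genome, example_guide) == brute_force_find_sites(
            example_genome, example_guide
        )

    def test_no_planted_site_empty(self):
        rng = np.random.default_rng(3)
        genome = NucSeq("g", "".join(rng.choice(list("ACGT"), size=1000)))
        guide = GuidePair("ACGUUGCAC", "GGCAUCCGA")
        assert brute_force_find_sites(genome, guide) == []
        assert find_sites(genome, guide) == []

    def test_planted_mismatch_recorded(self, example_guide):
        truth = make_target_genome(
            21, example_guide, n_sites=1, mismatch_spec=[[("A", 3)]], length=2000
        )
        sites = brute_force_find_sites(truth.seq, example_guide, max_mm_per_region=1)
        assert len(sites) == 1
        assert sites[0].mismatches_a == [3]
        assert sites[0].mismatches_b == []


class TestPredictCleavage:
    def test_perfect_site_geometry(self, example_genome, example_guide):
        site = find_sites(example_genome, example_guide)[0]
        call = predict_cleavage(site)
        assert call.outcome == "dsb"
        # footprint-local 1-based: bottom nick between 5|6, top between 13|14
        assert call.nick_a == 105
        assert call.nick_b == 113
        assert call.overhang_len == 8
        assert call.overhang_seq == "CGTATCCG"

    def test_seed_mismatch_abolishes_both_strands(self, example_guide):
        truth = make_target_genome(
            22, example_guide, n_sites=1, mismatch_spec=[[("B", 4)]], length=2000
        )
        site = find_sites(truth.seq, example_guide, max_mm_per_region=1)[0]
        assert predict_cleavage(site).outcome == "none"

    def test_nickase_mismatch_spares_other_strand(self, example_guide):
        truth = make_target_genome(
            23, example_guide, n_sites=1, mismatch_spec=[[("A", 6)]], length=2000
        )
        site = find_sites(truth.seq, example_guide, max_mm_per_region=1)[0]
        call = predict_cleavage(site)
        assert call.outcome == "nick_B_strand"
        assert call.nick_a is None and call.nick_b is not None

    def test_edge_single_tolerated_double_abolishes(self, example_guide):
        single = make_target_genome(
            24, example_guide, n_sites=1, mismatch_spec=[[("A", 9)]], length=2000
        )
        site = find_sites(single.seq, example_guide, max_mm_per_region=1)[0]
        assert predict_cleavage(site).outcome == "dsb"
        double = make_target_genome(
            25, example_guide, n_sites=1, mismatch_spec=[[("A", 8), ("A", 9)]], length=2000
        )
        site2 = find_sites(double.seq, example_guide, max_mm_per_region=2)[0]
        assert predict_cleavage(site2).outcome == "none"

    def test_gapped_overhang_is_8_plus_gap(self, example_guide):
        for gap in (1, 2):
            truth = make_target_genome(26 + gap, example_guide, gaps=(gap,), length=2000)
            site = find_sites(truth.seq, example_guide)[0]
            call = predict_cleavage(site)
            assert site.gap == gap
            assert call.overhang_len == 8 + gap

    def test_five_matched_bases_3prime_of_each_nick(self, example_genome, example_guide):
        site = find_sites(example_genome, example_guide)[0]
        call = predict_cleavage(site)
        # A-matched strand is the bottom strand: its 3' side is lower coords
        a_start, a_end, a_strand = site.region_a
        assert a_strand == "-"
        assert call.nick_a - a_start == 5
        b_start, b_end, b_strand = site.region_b
        assert b_strand == "+"
        assert b_end - call.nick_b == 5

    def test_invalid_mismatch_index_error(self, example_genome, example_guide):
        site = find_sites(example_genome, example_guide)[0]
        site.mismatches_a = [10]
        with pytest.raises(ValueError):
            predict_cleavage(site)


class TestGapScan:
    def test_boundary_at_two(self, example_guide):
        truth = make_target_genome(
            31, example_guide, n_sites=7, gaps=(0, 1, 2, 3, 4, 5, 6), length=8000
        )
        table = dict(gap_scan(truth.seq, example_guide))
        assert table == {0: True, 1: True, 2: True, 3: False, 4: False, 5: False, 6: False}


class TestSsDnaScan:
    def test_spacer_b_complement_match(self, example_guide):
        # ssDNA carrying the spacer-B-complementary 9-mer
        ss = NucSeq("ss", "TTTT" + "TCCGGATCC" + "TTTT")
        matches = ssdna_scan(ss, example_guide)
        assert len(matches) == 1
        m = matches[0]
        assert (m.spacer, m.start, m.end) == ("B", 4, 13)
        # nick between the bases pairing spacer positions 5 and 6
        assert m.nick == 4 + 9 - 5

    def test_rna_not_cleaved(self, example_guide):
        ss = NucSeq("ss", "UUUUUCCGGAUCCUUUU", "rna")
        assert ssdna_scan(ss, example_guide) == []

    def test_short_sequence_empty(self, example_guide):
        assert ssdna_scan(NucSeq("s", "ACGT"), example_guide) == []


class TestOffTargetScan:
    def test_decoy_ranked_below_perfect(self, example_guide):
        truth = make_target_genome(
            41, example_guide, n_sites=2, gaps=(0, 0),
            mismatch_spec=[[], [("B", 4)]], length=4000,
        )
        ranked = off_target_scan(truth.seq, example_guide, max_mm_per_region=1)
        assert len(ranked) == 2
        assert ranked[0][1].outcome == "dsb"
        assert ranked[1][1].outcome == "none"

    def test_empty_when_no_matches(self, example_guide):
        rng = np.random.default_rng(6)
        genome = NucSeq("g", "".join(rng.choice(list("ACGT"), size=500)))
        guide = GuidePair("ACGCGUUAC", "GGCACUCGA")
        assert off_target_scan(genome, guide, max_mm_per_region=0) == []

    def test_identical_sites_ordered_by_coordinate(self, example_guide):
        truth = make_target_genome(42, example_guide, n_sites=2, gaps=(0, 0), length=4000)
        ranked = off_target_scan(truth.seq, example_guide, max_mm_per_region=0)
        assert [r[0].start for r in ranked] == sorted(r[0].start for r in ranked)


class TestSelfTarget:
    def test_own_array_not_targeted(self, example_guide):
        construct, _ = build_expression_array(example_guide, TA_LIKE_REPEAT_SET)
        assert self_target_check(example_guide, construct) is False

    def test_construct_with_inserted_target(self, example_guide):
        construct, _ = build_expression_array(example_guide, TA_LIKE_REPEAT_SET)
        target18 = "ACGTACGTA" + "TCCGGATCC"
        combined = NucSeq("c", construct.seq + "TTTT" + target18 + "TTTT")
        assert self_target_check(example_guide, combined) is True

    def test_palindromic_spacer_corner_case_runs(self):
        # sA = revcomp(sB) in DNA space: the flagged design corner case
        guide = GuidePair("ACGUACGUA", "UACGUACGU")
        construct, _ = build_expression_array(guide, TA_LIKE_REPEAT_SET)
        assert isinstance(self_target_check(guide, construct), bool)


class TestMismatchModel:
    def test_disjoint_sets_required(self):
        with pytest.raises(ValueError):
            MismatchModel(seed_positions=frozenset({4, 5}), nickase_positions=frozenset({5, 6}))
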