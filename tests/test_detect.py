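import numpy as np
import pytest

from tigrkit import (
    NucSeq,
    DetectionParams,
    detect_dual_repeat_arrays,
    detect_stem_loop_arrays,
    predict_terminator,
    build_consensus,
    covariation_check,
    revcomp,
)
from tigrkit.fixtures import make_locus, make_repeat_set, make_stem_loop_locus
from tigrkit.seq import hamming


def _brute_force_periodicity(seq: str, period_range=(30, 50), win=8, max_mm=2) -> bool:
    """Independent oracle: is there any >=3-copy periodic repeat structure?"""
    for d in range(*period_range):
        for i in range(len(seq) - 2 * d - win):
            ref = seq[i : i + win]
            if (
                hamming(seq[i + d : i + d + win], ref) <= max_mm
                and hamming(seq[i + 2 * d : i + 2 * d + win], ref) <= max_mm
            ):
                return True
    return False


class TestDualRepeatDetection:
    def test_planted_array_exact_recovery(self):
        truth = make_locus(1, n_units=8, background_len=2000)
        calls = detect_dual_repeat_arrays(truth.seq)
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end) == (truth.array_start, truth.array_end)
        assert call.n_units == 8
        assert call.strand == "+"
        assert call.repeat_set.edge_repeat == truth.repeat_set.edge_repeat
        assert call.repeat_set.loop_repeat == truth.repeat_set.loop_repeat
        assert call.score == 1.0
        assert call.end - call.start == call.model.body_length

    def test_random_sequence_no_calls(self):
        rng = np.random.default_rng(78)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        # derived oracle: no (period, phase) supports >=3 near-identical copies
        assert not _brute_force_periodicity(seq)
        assert detect_dual_repeat_arrays(NucSeq("bg", seq)) == []

    def test_mutated_loops_recovered_with_counts(self):
        truth = make_locus(2, n_units=8, background_len=2000, per_copy_mutations=1)
        calls = detect_dual_repeat_arrays(truth.seq)
        assert len(calls) == 1
        assert calls[0].n_units == 8
        # injector wrote exactly one substitution into each loop copy
        assert calls[0].per_copy_mismatches[:8] == [1] * 8
        assert (calls[0].start, calls[0].end) == (truth.array_start, truth.array_end)

    def test_strand_symmetry(self):
        truth = make_locus(3, n_units=6, background_len=2000)
        plus = detect_dual_repeat_arrays(truth.seq)
        minus = detect_dual_repeat_arrays(revcomp(truth.seq))
        assert len(plus) == len(minus) == 1
        L = len(truth.seq)
        assert (L - minus[0].end, L - minus[0].start) == (plus[0].start, plus[0].end)
        assert {plus[0].strand, minus[0].strand} == {"+", "-"}

    def test_mismatch_monotonicity(self):
        truth = make_locus(4, n_units=8, background_len=2000, per_copy_mutations=1)
        units = []
        for mm in (0, 1, 2, 3):
            params = DetectionParams(max_mismatch_per_copy=mm)
            calls = detect_dual_repeat_arrays(truth.seq, params)
            units.append(sum(c.n_units for c in calls))
        assert units == sorted(units)

    def test_no_overlapping_calls_two_arrays(self):
        t1 = make_locus(5, n_units=5, background_len=1500)
        t2 = make_locus(6, n_units=7, background_len=1500)
        combined = NucSeq("two", t1.seq.seq + t2.seq.seq)
        calls = detect_dual_repeat_arrays(combined)
        assert len(calls) == 2
        assert calls[0].end <= calls[1].start
        starts = {c.start for c in calls}
        assert starts == {t1.array_start, len(t1.seq) + t2.array_start}

    def test_homopolymer_and_microsatellite_guard(self):
        rng = np.random.default_rng(13)
        mid = "".join(rng.choice(list("ACGT"), size=400))
        seq = NucSeq("lc", "A" * 300 + mid + "AT" * 150 + "CAG" * 100)
        assert detect_dual_repeat_arrays(seq) == []

    def test_terminator_annotated(self):
        truth = make_locus(7, n_units=8, background_len=2000, with_terminator=True)
        call = detect_dual_repeat_arrays(truth.seq)[0]
        assert call.model.has_terminator
        assert call.terminator is not None


class TestStemLoopDetection:
    def test_thirteen_units_three_subarrays(self):
        truth = make_stem_loop_locus(1)
        calls = detect_stem_loop_arrays(truth.seq)
        assert len(calls) == 3
        assert sum(c.n_units for c in calls) == 13
        assert [c.n_units for c in calls] == [5, 4, 4]
        got = [(u.start, u.end) for c in calls for u in c.units]
        assert got == truth.unit_intervals
        got_spacers = [(u.spacer_a, u.spacer_b) for c in calls for u in c.units]
        assert got_spacers == truth.spacers

    def test_hairpin_without_boxes_not_called(self):
        seq = NucSeq("h", "A" * 60 + "GCATGCC" + "AAAATTTTAAAA" + "GGCATGC" + "A" * 60)
        assert detect_stem_loop_arrays(seq) == []

    def test_broken_palindromy_drops_unit(self):
        truth = make_stem_loop_locus(3, break_palindromy_in=6)
        calls = detect_stem_loop_arrays(truth.seq)
        assert sum(c.n_units for c in calls) == len(truth.unit_intervals) - 1

    def test_box_offsets_annotated(self):
        truth = make_stem_loop_locus(2)
        calls = detect_stem_loop_arrays(truth.seq)
        u = calls[0].units[0]
        s = truth.seq.seq
        for off in u.boxC_offsets:
            assert s[off : off + 3] == "CCA"
        for off in u.boxD_offsets:
            assert s[off : off + 2] == "TG"


class TestTerminator:
    def test_perfect_hairpin_with_u_tract(self):
        seq = NucSeq("t", "GCGCGCGC" + "AAAA" + "GCGCGCGC" + "TTTTTTT" + "ACG")
        hit = predict_terminator(seq)
        assert hit is not None
        assert hit.stem_len == 8
        assert hit.u_tract_len == 7

    def test_no_u_tract_no_hit(self):
        seq = NucSeq("t", "GCGCGCGC" + "AAAA" + "GCGCGCGC" + "AAAAAAA")
        assert predict_terminator(seq) is None

    def test_random_window_no_hit(self):
        rng = np.random.default_rng(1236)
        s = "".join(rng.choice(list("ACGT"), size=200))
        # independent oracle: enumerate all hairpin geometries directly
        def oracle(seq):
            wc = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for i in range(len(seq)):
                for stem in range(6, 13):
                    for loop in range(3, 9):
                        j = i + stem + loop
                        if j + stem > len(seq):
                            continue
                        mism = sum(
                            1
                            for a, b in zip(seq[i : i + stem], reversed(seq[j : j + stem]))
                            if wc[a] != b
                        )
                        if mism <= 1 and seq[j + stem : j + stem + 8].count("T") >= 4:
                            return True
            return False

        assert not oracle(s)
        assert predict_terminator(NucSeq("r", s)) is None


class TestConsensus:
    def test_identical_copies(self):
        assert build_consensus(["TGGATCGCCA", "TGGATCGCCA"]) == "TGGATCGCCA"

    def test_iupac_two_way_column(self):
        # A and C each at 0.5 >= 0.25 threshold -> M
        assert build_consensus(["TGATCGCC", "TGCTCGCC"]) == "TGMTCGCC"

    def test_empty_error(self):
        with pytest.raises(ValueError):
            build_consensus([])

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            build_consensus(["ACGT", "ACG"])


class TestCovariation:
    def test_joint_divergence_full_covariation(self):
        # 4 of 10 loci change box D "TG"->"TA" jointly in edge and loop
        base_e, base_l = "TGGATCGCCA", "TGAAACCA"
        loci = []
        for i in range(10):
            if i < 4:
                loci.append(("TA" + base_e[2:], "TA" + base_l[2:]))
            else:
                loci.append((base_e, base_l))
        rep = covariation_check(loci, motif_positions=[0, 1])
        assert rep.identity_covariation == 1.0

    def test_independent_changes_counted(self):
        rng = np.random.default_rng(5)
        base_e, base_l = "TGGATCGCCA", "TGAAACCA"
        loci = []
        for _ in range(50):
            e = ("TA" if rng.random() < 0.5 else "TG") + base_e[2:]
            l = ("TA" if rng.random() < 0.5 else "TG") + base_l[2:]
            loci.append((e, l))
        rep = covariation_check(loci, motif_positions=[0, 1])
        direct = sum(1 for e, l in loci if e[:2] == l[:2]) / len(loci)
        assert rep.identity_covariation == direct

    def test_shared_repeat_set(self, ta_like):
        loci = [(ta_like.edge_repeat, ta_like.loop_repeat)] * 5
        rep = covariation_check(loci, motif_positions=[-3, -2, -1])
        assert rep.identity_covariation == 1.0

    def test_pair_positions(self):
        # positions 2 and 7 Watson-Crick paired within each repeat
        loci = [("TGATCGATCA", "TGATCGATCA"), ("TGGTCGACCA", "TGGTCGACCA")]
        rep = covariation_check(loci, [0, 1], pair_positions=[(2, 7)])
        assert rep.pair_complementarity[(2, 7)]["edge"] == 1.0

    def test_out_of_range_error(self, ta_like):
        with pytest.raises(IndexError):
            covariation_check(
                [(ta_like.edge_repeat, ta_like.loop_repeat)] * 2, [99]
            )

    def test_too_few_loci(self, ta_like):
        with pytest.raises(ValueError):
            covariation_check([(ta_like.edge_repeat, ta_like.loop_repeat)], [0])


class TestStemLoopMatureIntervals:
    def test_hairpin_with_slop(self):
        from tigrkit.detect import stem_loop_mature_intervals
        from tigrkit.fixtures import make_stem_loop_locus
        from tigrkit import detect_stem_loop_arrays

        truth = make_stem_loop_locus(4)
        call = detect_stem_loop_arrays(truth.seq)[0]
        ivs = stem_loop_mature_intervals(call, slop=3)
        assert len(ivs) == call.n_units
        for (s, e), u in zip(ivs, call.units):
            assert s <= u.start and e >= u.end
            assert e - s <= (u.end - u.start) + 6
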