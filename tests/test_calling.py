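"""Read QC, three-letter alignment, end filtering/masking and CpG calling."""

import math
import random

import numpy as np
import pytest

from drrbs.calling import (
    AlignedPair,
    AlignedRead,
    FastqRead,
    bisulfite_map,
    call_cpg_methylation,
    enzyme_end_filter_and_mask,
    estimate_conversion_rate,
    load_sam_pairs,
    qc_filter,
    transform_ct,
    transform_ga,
)
from drrbs.enzymes import merged_cut_sites
from drrbs.simulate import seq_to_array, array_to_seq, revcomp_array

from conftest import random_dna

Q35 = chr(35 + 33)
Q10 = chr(10 + 33)


def pair(seq1, seq2, qual1=None, qual2=None, name="r"):
    return (
        FastqRead(name, seq1, qual1 or Q35 * len(seq1)),
        FastqRead(name, seq2, qual2 or Q35 * len(seq2)),
    )


class TestQcFilter:
    def test_n_fraction_strictly_above_drops(self):
        bad = "N" * 31 + "A" * 69
        kept, log = qc_filter([pair(bad, "A" * 100)])
        assert kept == [] and log["pairs_dropped"] == 1

    def test_n_fraction_at_boundary_kept(self):
        edge = "N" * 30 + "A" * 70
        kept, _ = qc_filter([pair(edge, "A" * 100)])
        assert len(kept) == 1

    def test_low_quality_fraction(self):
        seq = "A" * 100
        kept, _ = qc_filter([pair(seq, seq, qual1=Q10 * 11 + Q35 * 89)])
        assert kept == []
        kept, _ = qc_filter([pair(seq, seq, qual1=Q10 * 10 + Q35 * 90)])
        assert len(kept) == 1

    def test_pair_dropped_if_either_mate_fails(self):
        kept, _ = qc_filter([pair("A" * 100, "N" * 40 + "A" * 60)])
        assert kept == []

    def test_length_mismatch_names_record(self):
        with pytest.raises(ValueError, match="bad_read"):
            qc_filter([(FastqRead("bad_read", "ACGT", "!!!"), FastqRead("bad_read", "ACGT", "!!!!"))])


class TestTransforms:
    def test_c_to_t(self):
        assert array_to_seq(transform_ct(seq_to_array("ACGT"))) == "ATGT"

    def test_g_to_a(self):
        assert array_to_seq(transform_ga(seq_to_array("ACGT"))) == "ACAT"


def _perfect_pair(genome_seq, start, insert, read_len=40, name="p", strand="top"):
    """Fully-methylated, fully-converted-free pair from the top or bottom
    strand (no conversion: original bases)."""
    frag = genome_seq[start : start + insert]
    if strand == "top":
        r1 = frag[:read_len]
        r2 = array_to_seq(revcomp_array(seq_to_array(frag)))[:read_len]
    else:
        bottom = array_to_seq(revcomp_array(seq_to_array(frag)))
        r1 = bottom[:read_len]
        r2 = frag[:read_len]
    return pair(r1, r2, name=name)


class TestBisulfiteMap:
    def test_unique_pair_placed_correctly(self):
        rng = np.random.default_rng(40)
        seq = random_dna(rng, 4_000)
        genome = {"c": seq}
        p = _perfect_pair(seq, 1000, 120, name="u")
        (ap,) = bisulfite_map([p], genome)
        assert ap.contig == "c" and ap.left == 1000 and ap.right == 1120
        assert ap.strand == "top"

    def test_bottom_strand_pair_recognized(self):
        rng = np.random.default_rng(41)
        seq = random_dna(rng, 4_000)
        genome = {"c": seq}
        p = _perfect_pair(seq, 700, 150, name="b", strand="bottom")
        (ap,) = bisulfite_map([p], genome)
        assert ap.strand == "bottom" and ap.left == 700 and ap.right == 850

    def test_converted_reads_still_map(self):
        """C->T changes on the read do not block placement (three-letter)."""
        rng = np.random.default_rng(42)
        seq = random_dna(rng, 4_000)
        genome = {"c": seq}
        frag = seq[2000:2130]
        converted = frag.replace("C", "T")  # fully unmethylated molecule
        r1 = converted[:50]
        r2 = array_to_seq(revcomp_array(seq_to_array(converted)))[:50]
        (ap,) = bisulfite_map([pair(r1, r2)], genome)
        assert ap.left == 2000 and ap.right == 2130

    def test_ambiguous_placement_discarded(self):
        rng = np.random.default_rng(43)
        block = random_dna(rng, 300)
        seq = block + random_dna(rng, 500) + block
        genome = {"c": seq}
        p = _perfect_pair(seq, 10, 100)
        assert bisulfite_map([p], genome) == []

    def test_excess_mismatches_discarded(self):
        rng = np.random.default_rng(44)
        seq = random_dna(rng, 3_000)
        genome = {"c": seq}
        frag = seq[500:600]
        r1 = list(frag[:40])
        for i in (5, 15, 25):  # three mismatches (A<->G never bisulfite-explained)
            r1[i] = {"A": "G", "G": "A", "C": "A", "T": "G"}[r1[i]]
        r2 = array_to_seq(revcomp_array(seq_to_array(frag)))[:40]
        assert bisulfite_map([pair("".join(r1), r2)], genome, max_mismatches=2) == []

    def test_input_order_invariance(self):
        rng = np.random.default_rng(45)
        seq = random_dna(rng, 6_000)
        genome = {"c": seq}
        ps = [
            _perfect_pair(seq, 100 + 137 * i, 110, name=f"p{i}")
            for i in range(20)
        ]
        fwd = bisulfite_map(ps, genome)
        shuffled = ps[:]
        random.Random(0).shuffle(shuffled)
        rev = bisulfite_map(shuffled, genome)
        key = lambda ap: (ap.r_fwd.read_id, ap.contig, ap.left, ap.right, ap.strand)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))


def _aligned(contig, start, bases, strand, mate, name="r", mask=0):
    arr = seq_to_array(bases)
    return AlignedRead(name, contig, start, start + len(arr), strand, mate, 0, arr, mask)


class TestEndFilterAndMask:
    @pytest.fixture
    def world(self, panel):
        # MspI site CCGG at 10 (cut 11); ApeKI GCAGC at 30 (cut 31)
        seq = "A" * 10 + "CCGG" + "A" * 16 + "GCAGC" + "A" * 15
        genome = {"c": seq}
        enz = {n: panel[n] for n in ("MspI", "ApeKI")}
        cuts = merged_cut_sites(genome, enz.values())
        return genome, enz, cuts

    def _pair_at(self, left, right, strand="top"):
        fwd = _aligned("c", left, "A" * 10, strand, "fwd")
        rev = _aligned("c", right - 10, "A" * 10, strand, "rev")
        if strand == "bottom":
            fwd, rev = (
                _aligned("c", right - 10, "A" * 10, strand, "fwd"),
                _aligned("c", left, "A" * 10, strand, "rev"),
            )
        return AlignedPair(fwd, rev, strand, "c", 0)

    def test_mspi_right_end_retained_mask_two(self, world):
        genome, enz, cuts = world
        # cut at 11, overhang 2 -> filled right boundary 13
        p = self._pair_at(0, 13, strand="top")
        kept, log = enzyme_end_filter_and_mask([p], cuts, enz)
        assert len(kept) == 1 and kept[0].r_rev.mask_len == 2

    def test_apeki_right_end_mask_three(self, world):
        genome, enz, cuts = world
        # ApeKI cut at 31, overhang 3 -> right boundary 34
        p = self._pair_at(20, 34, strand="top")
        kept, _ = enzyme_end_filter_and_mask([p], cuts, enz)
        assert len(kept) == 1 and kept[0].r_rev.mask_len == 3

    def test_left_end_bottom_strand_masked(self, world):
        genome, enz, cuts = world
        p = self._pair_at(11, 25, strand="bottom")  # left at MspI cut
        kept, _ = enzyme_end_filter_and_mask([p], cuts, enz)
        assert len(kept) == 1 and kept[0].r_rev.mask_len == 2

    def test_no_enzyme_end_dropped(self, world):
        genome, enz, cuts = world
        p = self._pair_at(2, 22, strand="top")
        kept, log = enzyme_end_filter_and_mask([p], cuts, enz)
        assert kept == [] and log["pairs_dropped"] == 1

    def test_mask_disabled_flag(self, world):
        genome, enz, cuts = world
        p = self._pair_at(0, 13, strand="top")
        kept, _ = enzyme_end_filter_and_mask([p], cuts, enz, apply_mask=False)
        assert kept[0].r_rev.mask_len == 0


class TestCallCpgMethylation:
    def test_vote_arithmetic(self):
        genome = {"c": "TTCGTT"}
        reads = []
        for i in range(7):
            reads.append(_aligned("c", 0, "TTCGTT", "top", "fwd", name=f"m{i}"))
        for i in range(3):
            reads.append(_aligned("c", 0, "TTTGTT", "top", "fwd", name=f"u{i}"))
        pairs = [
            AlignedPair(r, _aligned("c", 0, "T", "top", "rev", name=r.read_id + "x"), "top", "c", 0)
            for r in reads
        ]
        # keep the dummy rev reads off the CpG
        calls = call_cpg_methylation(pairs, genome)
        (call,) = calls
        assert (call.position, call.methylated, call.unmethylated) == (2, 7, 3)
        assert call.level == pytest.approx(0.7)

    def test_bottom_strand_votes_pool_to_same_cpg(self):
        genome = {"c": "TTCGTT"}
        top = _aligned("c", 0, "TTCGTT", "top", "fwd", name="t")
        bot_m = _aligned("c", 0, "TTCGTT", "bottom", "fwd", name="bm")  # G at 3
        bot_u = _aligned("c", 0, "TTCATT", "bottom", "fwd", name="bu")  # A at 3
        pairs = [
            AlignedPair(r, _aligned("c", 5, "T", s, "rev", name=r.read_id + "x"), s, "c", 0)
            for r, s in ((top, "top"), (bot_m, "bottom"), (bot_u, "bottom"))
        ]
        (call,) = call_cpg_methylation(pairs, genome)
        assert (call.position, call.methylated, call.unmethylated) == (2, 2, 1)

    def test_masked_positions_excluded(self):
        genome = {"c": "TTCGTT"}
        rev = _aligned("c", 0, "TTCGTT", "top", "rev", name="r", mask=4)
        # top-strand rev read masks its genome-right end [2, 6)
        p = AlignedPair(_aligned("c", 0, "T", "top", "fwd"), rev, "top", "c", 0)
        assert call_cpg_methylation([p], genome) == []

    def test_zero_coverage_absent(self):
        assert call_cpg_methylation([], {"c": "TTCGTT"}) == []


class TestConversionRate:
    def test_all_converted_is_one(self):
        genome = {"lambda_spike": "TTCCTT"}
        read = _aligned("lambda_spike", 0, "TTTTTT", "top", "fwd")
        p = AlignedPair(read, _aligned("lambda_spike", 0, "T", "top", "rev", name="x"),
                        "top", "lambda_spike", 0)
        assert estimate_conversion_rate([p], genome) == 1.0

    def test_no_coverage_undefined(self):
        with pytest.warns(UserWarning):
            assert math.isnan(estimate_conversion_rate([], {"lambda_spike": "CCC"}))

    def test_missing_contig_rejected(self):
        with pytest.raises(KeyError):
            estimate_conversion_rate([], {"c": "CCC"})


class TestSamImport:
    def test_roundtrip_matches_builtin(self, tmp_path):
        rng = np.random.default_rng(50)
        seq = random_dna(rng, 2_000)
        genome = {"c": seq}
        frag = seq[400:520]
        r1, r2 = frag[:50], array_to_seq(revcomp_array(seq_to_array(frag)))[:50]
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            f"@SQ\tSN:c\tLN:{len(seq)}\n"
            f"p1\t99\tc\t401\t60\t50M\t=\t471\t120\t{r1}\t{'I' * 50}\tXG:Z:CT\n"
            f"p1\t147\tc\t471\t60\t50M\t=\t401\t-120\t{frag[70:120]}\t{'I' * 50}\tXG:Z:CT\n"
        )
        (ap,) = load_sam_pairs(str(sam), genome)
        assert (ap.left, ap.right, ap.strand) == (400, 520, "top")
        assert array_to_seq(ap.r_fwd.bases) == r1
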