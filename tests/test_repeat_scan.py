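"""Tandem direct-repeat and terminal inverted-repeat detection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borgtools import (
    LinearGenome,
    classify_context,
    find_tandem_arrays,
    find_terminal_inverted_repeats,
    revcomp,
)
from borgtools.genome import decode
from borgtools.synthetic_data import _draw_codes

from oracles import brute_force_itr, brute_force_tandem_arrays


def _random_dna(rng, n, gc=0.45):
    return decode(_draw_codes(rng, n, gc))


def _as_set(arrays):
    return {(a.start, a.end, a.unit_len, a.copies, a.unit_seq) for a in arrays}


class TestFindTandemArrays:
    def test_planted_short_unit_resolved_from_overlapping_matches(self):
        # a 4 bp unit repeated 30x: the 120 bp span is reported with the
        # minimal period, not as a chain of 50 bp self-matches
        seq = "CC" + "ACGT" * 30 + "GG"
        arrays = find_tandem_arrays(seq, min_match=50, min_copies=3)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.start, a.end, a.unit_seq, a.unit_len, a.copies) == (2, 122, "ACGT", 4, 30)

    def test_reconstruction_unit_times_copies_equals_span(self, rng):
        seq = list(_random_dna(rng, 3000))
        unit = "ACGTTGCACGATCAGGTT"
        seq[500 : 500 + len(unit) * 5] = unit * 5
        seq = "".join(seq)
        for a in find_tandem_arrays(seq, min_match=50, min_copies=3):
            assert a.unit_seq * a.copies == seq[a.start : a.end]

    def test_no_arrays_in_unstructured_sequence(self, rng):
        seq = _random_dna(rng, 10_000)
        assert find_tandem_arrays(seq, min_match=50, min_copies=3) == []

    def test_equals_oracle_on_random_sequence(self, rng):
        seq = _random_dna(rng, 2_000, gc=0.5)
        got = _as_set(find_tandem_arrays(seq, min_match=50, min_copies=3))
        assert got == brute_force_tandem_arrays(seq, min_match=50, min_copies=3)

    @pytest.mark.parametrize(
        "seq",
        [
            "A" * 120,  # homopolymer: unit A, maximal copies
            "AT" * 80,  # dinucleotide
            "ACG" * 20 + "T" + "ACG" * 20,  # broken by one mismatch
            ("ACGTAC" * 12 + "TT") * 3,  # nested periodicities
            "ACGT" * 20 + "N" + "ACGT" * 20,  # N splits an array
            "AAAAAT" * 12,  # unit with internal homopolymer
        ],
    )
    def test_equals_oracle_on_adversarial_sequences(self, seq):
        for min_match, min_copies in ((50, 3), (20, 2), (10, 3)):
            got = _as_set(find_tandem_arrays(seq, min_match=min_match, min_copies=min_copies))
            assert got == brute_force_tandem_arrays(seq, min_match, min_copies)

    def test_homopolymer_reports_smallest_unit_maximal_copies(self):
        arrays = find_tandem_arrays("A" * 120, min_match=50, min_copies=3)
        assert len(arrays) == 1
        assert (arrays[0].unit_len, arrays[0].copies) == (1, 120)

    def test_arrays_never_span_n(self):
        seq = "ACGT" * 20 + "N" + "ACGT" * 20
        for a in find_tandem_arrays(seq, min_match=50, min_copies=3):
            assert "N" not in seq[a.start : a.end]

    def test_reverse_complement_symmetry(self, rng):
        seq = list(_random_dna(rng, 1_500))
        unit = "ACGGATTACCAGATTCAG"
        # blocker bases each side so the array has no partial-copy flank
        # (whole-copy trimming is only coordinate-symmetric for such arrays)
        seq[299 : 301 + len(unit) * 4] = "T" + unit * 4 + "C"
        seq = "".join(seq)
        fwd = find_tandem_arrays(seq, min_match=50, min_copies=3)
        rev = find_tandem_arrays(revcomp(seq), min_match=50, min_copies=3)
        L = len(seq)
        reflected = {
            (L - a.end, L - a.start, a.unit_len, a.copies) for a in rev
        }
        assert {(a.start, a.end, a.unit_len, a.copies) for a in fwd} == reflected

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=160), st.integers(2, 4))
    def test_matches_oracle_property(self, seq, min_copies):
        got = _as_set(find_tandem_arrays(seq, min_match=8, min_copies=min_copies))
        assert got == brute_force_tandem_arrays(seq, min_match=8, min_copies=min_copies)

    def test_empty_sequence_and_bad_parameters(self):
        assert find_tandem_arrays("") == []
        with pytest.raises(ValueError):
            find_tandem_arrays("ACGT", min_copies=1)


class TestClassifyContext:
    GENES = pd.DataFrame(
        {
            "contig": ["g", "g"],
            "gene_id": ["g_1", "g_2"],
            "start": [900, 3000],
            "end": [2000, 3900],
            "strand": ["+", "-"],
        }
    )

    def _array(self, start, end, unit_len):
        from borgtools.repeat_scan import RepeatArray

        return RepeatArray(
            genome_id="g", start=start, end=end,
            unit_seq="A" * unit_len, unit_len=unit_len,
            copies=(end - start) // unit_len,
        )

    @pytest.mark.parametrize(
        "start,end,unit_len,context,aa",
        [
            (1000, 1090, 9, "within_gene", False),  # (1000-900) % 3 == 1: out of frame
            (999, 1089, 9, "within_gene", True),  # (999-900) % 3 == 0: in frame
            (2100, 2190, 9, "intergenic", False),
            (1950, 2050, 10, "gene_overlapping", False),
            (3006, 3090, 12, "within_gene", True),  # minus strand, frame from gene end
        ],
    )
    def test_context_and_frame(self, start, end, unit_len, context, aa):
        a = classify_context(self._array(start, end, unit_len), self.GENES)
        assert (a.context, a.aa_repeat) == (context, aa)

    def test_no_genes_means_intergenic(self):
        a = classify_context(self._array(10, 100, 9), self.GENES.iloc[0:0])
        assert a.context == "intergenic"

    def test_in_frame_array_translates_to_perfect_residue_repeat(self):
        from Bio.Seq import Seq

        unit = "GCTAGCGATACT"  # 12 bp, 4 residues
        gene = "ATG" + "GGT" * 10 + unit * 4 + "GGC" * 10 + "TAA"
        prot = str(Seq(gene).translate())
        unit_aa = str(Seq(unit).translate())
        assert unit_aa * 4 in prot  # 4-residue tandem repeat at protein level
        genes = pd.DataFrame(
            {"contig": ["g"], "gene_id": ["g_1"], "start": [0],
             "end": [len(gene)], "strand": ["+"]}
        )
        start = 3 + 30
        a = classify_context(self._array(start, start + 48, 12), genes)
        assert a.context == "within_gene" and a.aa_repeat is True


class TestTerminalInvertedRepeats:
    def test_planted_itr_found_at_exact_length(self, rng):
        arm = _random_dna(rng, 1_500)
        core = _random_dna(rng, 6_000)
        hit = find_terminal_inverted_repeats(arm + core + revcomp(arm), min_len=100)
        assert hit is not None and hit.perfect
        assert hit.length >= 1_500  # may extend by chance matches at the junction
        assert hit.length - 1_500 <= 16
        assert hit.left_arm[0] == 0

    def test_random_sequence_has_no_itr(self, rng):
        seq = _random_dna(rng, 8_000)
        assert find_terminal_inverted_repeats(seq, min_len=100) is None
        assert brute_force_itr(seq, min_len=100) is None

    def test_matches_oracle_on_small_cases(self, rng):
        for n in (300, 500, 900):
            arm = _random_dna(rng, 120)
            seq = arm + _random_dna(rng, n) + revcomp(arm)
            got = find_terminal_inverted_repeats(seq, min_len=50)
            assert got is not None
            assert got.length == brute_force_itr(seq, min_len=50)

    def test_idempotent_after_trimming(self, rng):
        arm = _random_dna(rng, 400)
        seq = arm + _random_dna(rng, 4_000) + revcomp(arm)
        hit = find_terminal_inverted_repeats(seq, min_len=100)
        trimmed = seq[hit.length : len(seq) - hit.length]
        assert find_terminal_inverted_repeats(trimmed, min_len=100) is None

    def test_mismatch_tolerance(self, rng):
        arm = _random_dna(rng, 1_000)
        right = list(revcomp(arm))
        right[500] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[500]]
        seq = arm + _random_dna(rng, 3_000) + "".join(right)
        assert find_terminal_inverted_repeats(seq, min_len=800, max_mismatch_frac=0.0) is None
        hit = find_terminal_inverted_repeats(seq, min_len=800, max_mismatch_frac=0.01)
        assert hit is not None and hit.length >= 1_000 and not hit.perfect

    def test_too_short_genome_returns_none(self):
        assert find_terminal_inverted_repeats("ACGTACGT", min_len=100) is None

    def test_circular_topology_rejected(self):
        g = LinearGenome(id="c", seq="ACGT" * 100, topology="circular")
        with pytest.raises(ValueError):
            find_terminal_inverted_repeats(g)
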