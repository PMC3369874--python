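import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevnet.errors import (
    AlignmentShapeError,
    EmptyInputError,
    MissingReferenceError,
    UndefinedEntropyError,
    UndefinedIdentityError,
)
from coevnet.msa import (
    AMINO_ACIDS,
    Alignment,
    column_entropy,
    column_profile,
    conservation_profile,
    deduplicate_by_identity,
    entropy_from_counts,
    filter_by_length,
    pairwise_identity,
    read_fasta_alignment,
    truncate_to_reference,
    write_fasta_alignment,
)

LOG20_2 = math.log(2) / math.log(20)


class TestFastaIO:
    def test_parse_two_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC-D\n>b\nAC-E\n")
        aln = read_fasta_alignment(p)
        assert (aln.n_seqs, aln.n_cols) == (2, 4)
        assert aln.records == [("a", "AC-D"), ("b", "AC-E")]

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACDE\n>b\nACDEF\n")
        with pytest.raises(AlignmentShapeError):
            read_fasta_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_fasta_alignment(p)

    def test_round_trip_preserves_records(self, tmp_path, small_alignment):
        p = tmp_path / "rt.fasta"
        write_fasta_alignment(small_alignment, p)
        assert read_fasta_alignment(p).records == small_alignment.records

    def test_nonstandard_letters_become_gaps(self, tmp_path):
        p = tmp_path / "odd.fasta"
        p.write_text(">a\nAXBZ\n>b\nacud\n")
        aln = read_fasta_alignment(p)
        assert aln.records == [("a", "A---"), ("b", "AC-D")]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Alignment([("a", "ACD"), ("a", "ACE")])


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept",
        [(399, False), (400, True), (450, True), (500, True), (501, False)],
    )
    def test_window_boundaries_inclusive(self, length, kept):
        seqs = ["A" * length]
        assert (filter_by_length(seqs) == seqs) is kept

    def test_order_preserved(self):
        seqs = ["A" * 450, "A" * 300, "A" * 420]
        assert filter_by_length(seqs) == ["A" * 450, "A" * 420]


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDE", "ACDE", 1.0),
            ("ACDE", "WYHK", 0.0),
            ("AC-D", "AC-E", 2 / 3),
            ("A-CD", "AC-E", 1 / 2),  # only cols 0,3 mutually non-gap
        ],
    )
    def test_identity_over_mutually_nongapped(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)
        assert pairwise_identity(b, a) == pytest.approx(expected)

    def test_no_overlap_is_undefined(self):
        with pytest.raises(UndefinedIdentityError):
            pairwise_identity("A--", "-CD")


class TestDeduplication:
    def test_exact_duplicates_collapse(self):
        aln = Alignment([("a", "ACDE"), ("b", "ACDE")])
        assert deduplicate_by_identity(aln).ids == ["a"]

    def test_diverse_set_untouched(self):
        aln = Alignment([("a", "ACDEF"), ("b", "AGHIF"),
                         ("c", "MNPQR"), ("d", "WCDYV")])
        out = deduplicate_by_identity(aln, cutoff=0.90)
        assert out.ids == ["a", "b", "c", "d"]

    def test_copies_plus_diverse(self):
        base = "ACDEFGHIKL"
        diverse = ["MNPQRSTVWY", "CADEGFHKIL"[::-1], "WYVTSRQPNM",
                   "KLIHGFEDCA", "YVWTSRQPMN"]
        records = [(f"c{i}", base) for i in range(10)]
        records += [(f"d{i}", s) for i, s in enumerate(diverse)]
        out = deduplicate_by_identity(Alignment(records), cutoff=0.90)
        assert out.n_seqs == 6
        # survivors: first copy + the diverse ones; no retained pair above cutoff
        for i in range(out.n_seqs):
            for j in range(i + 1, out.n_seqs):
                assert pairwise_identity(out.seqs[i], out.seqs[j]) <= 0.90

    def test_greedy_keeps_first_in_file_order(self):
        aln = Alignment([("later_dup", "ACDE"), ("other", "WYHK"),
                         ("dup", "ACDE")])
        assert deduplicate_by_identity(aln).ids == ["later_dup", "other"]


class TestReferenceTruncation:
    def test_gapped_reference_columns_dropped(self):
        aln = Alignment([("ref", "A-CD"), ("x", "AWCE")])
        out, rmap = truncate_to_reference(aln, "ref")
        assert out.records == [("ref", "ACD"), ("x", "ACE")]
        assert rmap.col_to_refpos == {0: 1, 1: 2, 2: 3}
        assert rmap.source_columns == (0, 2, 3)

    def test_ungapped_reference_is_identity(self, small_alignment):
        out, rmap = truncate_to_reference(small_alignment, "s2")
        assert out.records == small_alignment.records
        assert len(rmap) == small_alignment.n_cols

    def test_missing_reference(self, small_alignment):
        with pytest.raises(MissingReferenceError):
            truncate_to_reference(small_alignment, "nope")

    def test_reference_row_recovers_ungapped_sequence(self):
        aln = Alignment([("ref", "-AC--DE-F"), ("x", "GACWWDEFF")])
        out, _ = truncate_to_reference(aln, "ref")
        assert out.row("ref") == "ACDEF"


class TestEntropy:
    def test_conserved_column_is_zero(self):
        assert entropy_from_counts({"A": 150}) == 0.0

    def test_uniform_twenty_types_is_one(self):
        assert entropy_from_counts({aa: 5 for aa in AMINO_ACIDS}) == pytest.approx(1.0)

    def test_two_state_column(self):
        assert entropy_from_counts({"D": 50, "E": 50}) == pytest.approx(LOG20_2)

    def test_all_gap_column_undefined(self):
        aln = Alignment([("a", "-A"), ("b", "-C")])
        with pytest.raises(UndefinedEntropyError):
            column_entropy(column_profile(aln, 0))

    def test_profile_counts_and_gap_fraction(self):
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "C"), ("d", "-")])
        prof = column_profile(aln, 0)
        assert prof.counts == {"A": 2, "C": 1}
        assert prof.gap_fraction == pytest.approx(0.25)

    @given(st.permutations(list("AAAACCDDEF")))
    @settings(max_examples=25, derandomize=True)
    def test_row_permutation_invariance(self, letters):
        aln = Alignment([(f"s{i}", ch) for i, ch in enumerate(letters)])
        assert column_entropy(column_profile(aln, 0)) == pytest.approx(
            entropy_from_counts({"A": 4, "C": 2, "D": 2, "E": 1, "F": 1})
        )


class TestConservationProfile:
    def test_conserved_ungapped_scores_zero(self):
        aln = Alignment([(f"s{i}", "A") for i in range(10)])
        assert conservation_profile(aln)[0] == 0.0

    def test_heavily_gapped_column_forced_to_one(self):
        rows = [("g", "-")] + [(f"s{i}", "A") for i in range(8)]
        aln = Alignment(rows)  # 1/9 gapped ~ 11%
        assert conservation_profile(aln)[0] == 1.0

    def test_exactly_ten_percent_not_forced(self):
        rows = [("g", "-")] + [(f"s{i}", "A") for i in range(9)]
        aln = Alignment(rows)  # exactly 10% gapped
        assert conservation_profile(aln)[0] == 0.0
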