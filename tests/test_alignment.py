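import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evosig.alignment import (
    Alignment,
    pairwise_identity,
    read_alignment,
    read_annotation,
    read_score_table,
    reduce_redundancy,
    trim_to_reference,
    write_alignment,
)
from evosig.errors import (
    InputError,
    ParseError,
    ReferenceNotFoundError,
    ValidationError,
)
from conftest import make_alignment


class TestReadAlignment:
    def test_fasta_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIKM\n>c\nACDE.GHIKL\n")
        aln = read_alignment(p, "fasta")
        assert aln.n_sequences == 3
        assert aln.n_columns == 10
        assert aln.seqs[2] == "ACDE-GHIKL"  # '.' normalized to '-'

    def test_stockholm_gap_normalization(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text(
            "# STOCKHOLM 1.0\nseq1 AC.E\nseq2 ACDE\n//\n"
        )
        aln = read_alignment(p, "stockholm")
        assert aln.seqs[0] == "AC-E"

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacde\n>b\nAC-E\n")
        assert read_alignment(p).seqs[0] == "ACDE"

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACDE\n>b\nACD\n")
        with pytest.raises((ValidationError, ParseError)):
            read_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(InputError):
            read_alignment(p)

    def test_roundtrip(self, tmp_path, toy_alignment):
        p = tmp_path / "out.fasta"
        write_alignment(toy_alignment, p)
        back = read_alignment(p, reference_id="ref")
        assert back.ids == toy_alignment.ids
        assert back.seqs == toy_alignment.seqs


class TestTrim:
    def test_gapfree_reference_identity(self):
        aln = make_alignment(["ACDE", "AC-E"], reference_id="ref", trimmed=False)
        out = trim_to_reference(aln)
        assert out.seqs == aln.seqs
        assert list(out.column_map) == [1, 2, 3, 4]

    def test_reference_gap_columns_removed(self):
        aln = Alignment(ids=["ref", "x"], seqs=["A-C", "AGC"], reference_id="ref")
        out = trim_to_reference(aln)
        assert out.reference_sequence == "AC"
        assert out.seqs[1] == "AC"
        assert list(out.column_map) == [1, 2]

    def test_idempotent(self):
        aln = Alignment(ids=["ref", "x"], seqs=["A--CD", "AGGCD"], reference_id="ref")
        once = trim_to_reference(aln)
        twice = trim_to_reference(once)
        assert once.seqs == twice.seqs
        assert list(once.column_map) == list(twice.column_map)

    def test_all_gap_reference_rejected(self):
        aln = Alignment(ids=["ref", "x"], seqs=["---", "AGC"], reference_id="ref")
        with pytest.raises(ValidationError):
            trim_to_reference(aln)

    def test_missing_reference(self):
        aln = Alignment(ids=["a", "b"], seqs=["AC", "AC"])
        with pytest.raises(ReferenceNotFoundError):
            trim_to_reference(aln, "nope")


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("ACDE", "ACDE", 1.0),
            ("ACDE", "GHIK", 0.0),
            ("AAC-", "AAG-", 2.0 / 3.0),  # 3 comparable columns, 2 identical
            ("A-C-", "AGC-", 2.0 / 3.0),  # gap vs residue counts in denominator
            ("--", "--", 0.0),
        ],
    )
    def test_examples(self, s1, s2, expected):
        assert pairwise_identity(s1, s2) == pytest.approx(expected)

    def test_symmetry(self):
        assert pairwise_identity("AC-E", "GCDE") == pairwise_identity("GCDE", "AC-E")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_identity("ACD", "AC")


class TestReduceRedundancy:
    def test_all_identical_keeps_reference_only(self):
        aln = make_alignment(["ACDE"] * 5, reference_id="ref")
        out = reduce_redundancy(aln, 0.62)
        assert out.ids == ["ref"]

    def test_all_distant_kept(self):
        aln = make_alignment(["ACDE", "GHIK", "LMNP", "QRST"], reference_id="ref")
        out = reduce_redundancy(aln, 0.62)
        assert out.n_sequences == 4

    def test_greedy_trace(self):
        # ref + 3 near-copies (90% id to ref) + one remote sequence -> 2 kept
        ref = "ACDEFGHIKL"
        near = ["ACDEFGHIKM", "ACDEFGHIKV", "ACDEFGHIKW"]
        far = "PWNQYSTRVM"
        aln = make_alignment([ref] + near + [far], reference_id="ref")
        out = reduce_redundancy(aln, 0.62)
        assert out.ids == ["ref", "s4"]

    def test_threshold_one_removes_exact_duplicates_only(self):
        aln = make_alignment(["ACDE", "ACDE", "ACDF"], reference_id="ref")
        out = reduce_redundancy(aln, 1.0)
        assert out.seqs == ["ACDE", "ACDF"]

    @given(
        st.lists(
            st.text(alphabet="ACDG-", min_size=8, max_size=8), min_size=2, max_size=12
        ),
        st.floats(min_value=0.2, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_no_kept_pair_reaches_threshold(self, seqs, threshold):
        aln = make_alignment(seqs, trimmed=True)
        out = reduce_redundancy(aln, threshold)
        for i in range(out.n_sequences):
            for j in range(i + 1, out.n_sequences):
                assert pairwise_identity(out.seqs[i], out.seqs[j]) < threshold


class TestScoreTable:
    def test_full_table(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("# header\n1\t0.5\n2\t1.5\n3\t-0.25\n")
        sv = read_score_table(p)
        assert list(sv.values) == [0.5, 1.5, -0.25]
        assert not sv.missing.any()

    def test_missing_position_flagged(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("1\t1.0\n2\t2.0\n4\t4.0\n5\t5.0\n")
        sv = read_score_table(p, length=5)
        assert sv.missing.tolist() == [False, False, True, False, False]

    def test_duplicate_position_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("1\t1.0\n1\t2.0\n")
        with pytest.raises(ParseError):
            read_score_table(p)

    def test_non_numeric_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("1\t1.0\n2\txyz\n")
        with pytest.raises(ParseError):
            read_score_table(p)

    def test_roundtrip(self, tmp_path):
        from evosig.alignment import ScoreVector, write_score_table

        sv = ScoreVector("m", np.array([1.0, np.nan, 3.5]), "lower_better")
        p = tmp_path / "out.tsv"
        write_score_table(sv, p)
        back = read_score_table(p, orientation="lower_better", length=3)
        np.testing.assert_array_equal(back.missing, sv.missing)
        np.testing.assert_allclose(back.values[~back.missing], [1.0, 3.5])


class TestAnnotation:
    def test_parse(self, tmp_path):
        p = tmp_path / "ann.txt"
        p.write_text("10 25,77\n")
        ann = read_annotation(p, 100)
        assert ann.positions == {10, 25, 77}

    @pytest.mark.parametrize("content", ["0\n", "101\n"])
    def test_out_of_range_rejected(self, tmp_path, content):
        p = tmp_path / "ann.txt"
        p.write_text(content)
        with pytest.raises(ValidationError):
            read_annotation(p, 100)

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "ann.txt"
        p.write_text("\n")
        with pytest.raises(InputError):
            read_annotation(p, 100)
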