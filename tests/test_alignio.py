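"""FASTA I/O, the length filter, global alignment and reference numbering."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feadh.alignio import (
    AMINO_ACIDS,
    AlignConfig,
    DEFAULT_CONFIG,
    FastaError,
    ProteinRecord,
    filter_by_length,
    global_align,
    align_score,
    map_to_reference,
    read_fasta,
    write_fasta,
)
from tests.conftest import brute_force_affine_score


class TestFasta:
    def test_round_trip_with_taxon_groups(self, tmp_path):
        records = [
            ProteinRecord(id="q1", residues="ACDEFG", taxon_group="fungi"),
            ProteinRecord(id="q2", residues="MKLVX", taxon_group="bacteria"),
            ProteinRecord(id="q3", residues="WYY"),
        ]
        path = tmp_path / "seqs.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [r.id for r in back] == ["q1", "q2", "q3"]
        assert [r.residues for r in back] == ["ACDEFG", "MKLVX", "WYY"]
        assert [r.taxon_group for r in back] == ["fungi", "bacteria", "unknown"]

    def test_taxon_token_parsed_from_header(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">q1 some description taxon=fungi more\nACDE\n")
        (rec,) = read_fasta(path)
        assert rec.taxon_group == "fungi"

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(FastaError, match="no FASTA records"):
            read_fasta(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACDE\n>a\nMKLV\n")
        with pytest.raises(FastaError, match="duplicate id"):
            read_fasta(path)

    def test_illegal_residue_rejected_with_position(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACBDE\n")
        with pytest.raises(FastaError, match="'B' at position 3"):
            read_fasta(path)

    def test_empty_sequence_rejected(self):
        with pytest.raises(FastaError):
            ProteinRecord(id="x", residues="")


class TestLengthFilter:
    def test_strictly_greater_than_threshold(self):
        records = [
            ProteinRecord(id=f"s{n}", residues="A" * n) for n in (150, 200, 201, 400)
        ]
        kept = filter_by_length(records, threshold=200)
        assert [r.id for r in kept] == ["s201", "s400"]

    def test_uniform_full_length_all_kept(self):
        records = [ProteinRecord(id=f"s{i}", residues="A" * 467) for i in range(5)]
        assert filter_by_length(records) == records

    def test_empty_input(self):
        assert filter_by_length([]) == []


class TestGlobalAlign:
    def test_self_alignment_is_full_identity(self):
        aln = global_align("MKWVTFISLLFLFSSAYS", "MKWVTFISLLFLFSSAYS")
        assert aln.percent_identity == 100.0
        assert aln.aligned_a == aln.aligned_b

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACDE")

    def test_degapped_rows_equal_inputs(self):
        aln = global_align("ACDEFGHIK", "ACDFGHK")
        assert aln.aligned_a.replace("-", "") == "ACDEFGHIK"
        assert aln.aligned_b.replace("-", "") == "ACDFGHK"

    def test_score_matches_exhaustive_enumeration(self):
        rng = random.Random(7)
        for _ in range(40):
            a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 6)))
            assert align_score(a, b) == pytest.approx(
                brute_force_affine_score(a, b, DEFAULT_CONFIG)
            ), (a, b)

    def test_score_symmetric_under_symmetric_matrix(self):
        rng = random.Random(3)
        for _ in range(10):
            a = "".join(rng.choice(AMINO_ACIDS) for _ in range(30))
            b = "".join(rng.choice(AMINO_ACIDS) for _ in range(25))
            assert align_score(a, b) == pytest.approx(align_score(b, a))

    def test_x_never_counts_as_identity(self):
        aln = global_align("AXA", "AXA")
        # 2 of 3 columns identical (X-X excluded)
        assert aln.percent_identity == pytest.approx(100.0 * 2 / 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=12))
    def test_identity_never_exceeds_similarity(self, seq):
        shuffled = seq[::-1]
        aln = global_align(seq, shuffled)
        assert 0.0 <= aln.percent_identity <= aln.percent_similarity <= 100.0

    def test_deterministic_repeated_calls(self):
        a, b = "ACDEFGHIKLMNPQ", "ACDGHKLMNQ"
        first = global_align(a, b)
        second = global_align(a, b)
        assert first == second


class TestReferenceNumbering:
    def test_identity_mapping_on_self(self):
        rec = ProteinRecord(id="r", residues="MKWVTFISLL")
        numbering = map_to_reference(rec, rec)
        assert numbering.coverage == 1.0
        assert not numbering.low_confidence
        assert numbering.ref_to_query == {i: i for i in range(1, 11)}

    def test_reference_insert_left_unmapped(self):
        # reference carries a 19-residue block absent from the query
        left = "MKWVTFISLLFLFSSAYSRG"
        insert = "W" * 19
        right = "VFRRDAHKSEVAHRFKDLGE"
        reference = ProteinRecord(id="ref", residues=left + insert + right)
        query = ProteinRecord(id="q", residues=left + right)
        numbering = map_to_reference(query, reference)
        unmapped = [p for p in range(21, 40) if p not in numbering.ref_to_query]
        assert len(unmapped) == 19
        assert numbering.ref_to_query[20] == 20
        assert numbering.ref_to_query[40] == 21

    def test_nterminal_extension_shifts_query_positions(self):
        core = "MKWVTFISLLFLFSSAYSRGVFRR"
        reference = ProteinRecord(id="ref", residues=core)
        query = ProteinRecord(id="q", residues="G" * 10 + core)
        numbering = map_to_reference(query, reference)
        assert all(
            numbering.ref_to_query[p] == p + 10 for p in range(1, len(core) + 1)
        )

    def test_mapping_round_trip_is_identity(self, dataset):
        rec = dataset.records[0]
        numbering = map_to_reference(rec, dataset.reference)
        for qpos, rpos in numbering.query_to_ref.items():
            assert numbering.ref_to_query[rpos] == qpos

    def test_low_coverage_flagged_not_fatal(self):
        reference = ProteinRecord(id="ref", residues="MKWVTFISLLFLFSSAYSRGVFRR")
        query = ProteinRecord(id="q", residues="MKW")
        numbering = map_to_reference(query, reference, min_coverage=0.5)
        assert numbering.low_confidence
        assert numbering.coverage < 0.5
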