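"""Sequence I/O, pairwise global alignment and ADHFE1 reference numbering.

FeADH diagnostic rules are all phrased in coordinates of the 467-residue human
ADHFE1 protein.  This module provides the machinery to get a query sequence
into that frame: FASTA parsing with optional ``taxon=`` header metadata, the
family-standard length filter (sequences must exceed 200 residues, since true
FeADHs are ~400 aa), affine-gap Needleman-Wunsch alignment under BLOSUM62, and
the column-wise position map between a query and the reference.

Identity/similarity conventions (configurable, stated explicitly because the
literature rarely defines them): percent identity counts columns whose two
residues are equal (``X`` never counts), percent similarity counts aligned
residue pairs with a positive substitution score; both use all alignment
columns as denominator, so gaps count against both metrics.  The affine gap
convention is score = gap_open for the first gapped column of a run plus
gap_extend for each subsequent column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "TAXON_GROUPS",
    "ProteinRecord",
    "PairwiseAlignment",
    "ReferenceNumbering",
    "AlignConfig",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "global_align",
    "align_score",
    "map_to_reference",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet accepted in input sequences (X = unknown residue).
ALPHABET = frozenset(AMINO_ACIDS + "X")

TAXON_GROUPS = (
    "animal",
    "fungi",
    "viridiplantae",
    "other_eukaryote",
    "bacteria",
    "archaea",
    "unknown",
)

EUKARYOTE_GROUPS = frozenset({"animal", "fungi", "viridiplantae", "other_eukaryote"})


class FastaError(ValueError):
    """Malformed FASTA input (empty file, duplicate id, illegal residue)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional coarse taxonomic origin."""

    id: str
    residues: str
    description: str = ""
    taxon_group: str = "unknown"

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"record {self.id!r}: empty sequence")
        if self.taxon_group not in TAXON_GROUPS:
            raise FastaError(
                f"record {self.id!r}: unknown taxon group {self.taxon_group!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignConfig:
    """Substitution matrix and affine gap penalties for global alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        return aligner


DEFAULT_CONFIG = AlignConfig()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


@dataclass(frozen=True)
class ReferenceNumbering:
    """Partial bijection between query and reference positions (both 1-based).

    ``query_to_ref``/``ref_to_query`` cover exactly the alignment columns where
    neither sequence is gapped; ``coverage`` is the fraction of reference
    positions mapped.  ``low_confidence`` flags mappings whose coverage fell
    below the configured minimum — the map is still returned.
    """

    query_id: str
    ref_id: str
    query_to_ref: dict[int, int] = field(repr=False)
    ref_to_query: dict[int, int] = field(repr=False)
    coverage: float = 0.0
    low_confidence: bool = False

    def residue_at_ref(self, query: str, ref_pos: int) -> str:
        """Query residue aligned to a reference position, or ``'-'``."""
        qpos = self.ref_to_query.get(ref_pos)
        return query[qpos - 1] if qpos is not None else "-"


def _parse_taxon(description: str) -> str:
    for token in description.split():
        if token.startswith("taxon="):
            value = token[len("taxon=") :]
            if value not in TAXON_GROUPS:
                raise FastaError(f"unknown taxon group {value!r} in header")
            return value
    return "unknown"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA file into :class:`ProteinRecord` objects.

    The optional header token ``taxon=<group>`` sets ``taxon_group``; records
    without it are ``unknown``.  Rejects empty files, duplicate ids and
    residues outside the 20-letter alphabet plus ``X``, reporting the
    offending record and position.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaError(f"{path.name}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        for i, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise FastaError(
                    f"{path.name}: record {entry.id!r} has illegal residue "
                    f"{ch!r} at position {i}"
                )
        records.append(
            ProteinRecord(
                id=entry.id,
                residues=seq,
                description=entry.description,
                taxon_group=_parse_taxon(entry.description),
            )
        )
    if not records:
        raise FastaError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, encoding taxon_group as a ``taxon=`` token."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id} taxon={rec.taxon_group}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def filter_by_length(
    records: Sequence[ProteinRecord], threshold: int = 200
) -> list[ProteinRecord]:
    """Keep records strictly longer than ``threshold`` residues.

    Partial database entries shorter than half the family's typical ~400
    residues carry too few diagnostic positions to annotate or place reliably.
    """
    return [rec for rec in records if len(rec) > threshold]


def global_align(
    a: str, b: str, config: AlignConfig = DEFAULT_CONFIG
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences with affine gap costs.

    Ties between co-optimal alignments are broken deterministically (the
    aligner's canonical first traceback), so repeated calls are byte-identical.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = config.make_aligner()
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix
    n_cols = len(aligned_a)
    n_ident = 0
    n_sim = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb and ca != "X":
            n_ident += 1
        if matrix[ca, cb] > 0:
            n_sim += 1
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        percent_identity=100.0 * n_ident / n_cols,
        percent_similarity=100.0 * n_sim / n_cols,
    )


def align_score(a: str, b: str, config: AlignConfig = DEFAULT_CONFIG) -> float:
    """Alignment score only (no traceback) — used for bulk seed scoring."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return float(config.make_aligner().score(a, b))


def map_to_reference(
    query: ProteinRecord,
    reference: ProteinRecord,
    config: AlignConfig = DEFAULT_CONFIG,
    min_coverage: float = 0.5,
) -> ReferenceNumbering:
    """Map query positions onto reference numbering via global alignment.

    Only alignment columns where both sequences carry a residue enter the map;
    reference positions deleted in the query (e.g. the HOT insert spans in a
    non-HOT query) are simply absent from ``ref_to_query``.
    """
    aln = global_align(query.residues, reference.residues, config)
    q2r: dict[int, int] = {}
    r2q: dict[int, int] = {}
    qpos = rpos = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            qpos += 1
        if cb != "-":
            rpos += 1
        if ca != "-" and cb != "-":
            q2r[qpos] = rpos
            r2q[rpos] = qpos
    coverage = len(r2q) / len(reference)
    return ReferenceNumbering(
        query_id=query.id,
        ref_id=reference.id,
        query_to_ref=q2r,
        ref_to_query=r2q,
        coverage=coverage,
        low_confidence=coverage < min_coverage,
    )
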