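"""Rule-based functional annotation of FeADH sequences.

All rules read residues at ADHFE1-numbered anchor positions obtained through
:func:`feadh.alignio.map_to_reference`:

coenzyme preference (position 81)
    Asp/Thr at 81 mark NAD+ binders (the carboxylate/hydroxyl contacts the
    adenine-ribose 2'-OH and repels the 2'-phosphate of NADP+); Gly leaves
    room for the 2'-phosphate, permitting NADP+ or dual use.  Glu is treated
    like Asp (charge-conservative extension); Ser is deliberately left
    ambiguous — within this family Thr-carrying enzymes crystallized with
    NAD+, so a Ser rule would be an invention.

metal dependence (tetrad 242/246/330/357)
    The canonical Asp-His-His-His tetrad coordinates a divalent cation.
    Substitution of Asp242 by Asn/Arg (maleylacetate reductases) or Gln
    weakens metal affinity; such enzymes work without metal.

glycerol-dehydrogenase exclusion
    GDH-like sequences (a related but separate family) retain only the
    His357-equivalent of the tetrad; queries with His at 357 but neither
    His246 nor His330 are flagged and refused by the classifier.

GGGS motif (138-141), HOT insertions (256-274, 342-354), catalytic position
334 and the N/C-domain split (1-229 / 230-467) complete the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alignio import (
    AlignConfig,
    DEFAULT_CONFIG,
    ProteinRecord,
    ReferenceNumbering,
    map_to_reference,
)
from .registry import ANCHORS, AnchorMap, Span

__all__ = [
    "AnnotationResult",
    "call_coenzyme",
    "call_metal",
    "flag_gdh_like",
    "detect_gggs",
    "detect_hot_inserts",
    "annotate",
]

GAP = "-"

# Default minimum residue counts across the two insert spans for a hot_like
# call: ~80% of 19 and ~70% of 13, tolerating a little alignment slop.
HOT_INSERT_MINIMA = (15, 9)


@dataclass(frozen=True)
class AnnotationResult:
    """All diagnostic-residue calls for one query sequence."""

    query_id: str
    res81: str
    coenzyme_call: str  # NAD | NADP_or_dual | ambiguous
    tetrad: tuple[str, str, str, str]
    metal_call: str  # metal_dependent | metal_independent_likely | indeterminate
    gggs_present: bool
    res334: str
    insert1_len: int
    insert2_len: int
    hot_like: bool
    gdh_like: bool
    nterm_span: Span | None
    cterm_span: Span | None
    coverage: float
    low_confidence: bool


def call_coenzyme(res81: str) -> str:
    """Coenzyme preference from the residue at position 81."""
    if res81 in ("D", "E", "T"):
        return "NAD"
    if res81 in ("G", "A"):
        return "NADP_or_dual"
    return "ambiguous"


def call_metal(tetrad: Sequence[str]) -> str:
    """Metal dependence from the residues at the 242/246/330/357 tetrad."""
    d, h1, h2, h3 = tetrad
    if (d, h1, h2, h3) == ("D", "H", "H", "H"):
        return "metal_dependent"
    if d in ("N", "R", "Q") and (h1, h2, h3) == ("H", "H", "H"):
        return "metal_independent_likely"
    return "indeterminate"


def flag_gdh_like(tetrad: Sequence[str]) -> bool:
    """True when only the His357-equivalent of the tetrad is conserved."""
    _, h246, h330, h357 = tetrad
    return h357 == "H" and h246 != "H" and h330 != "H"


def detect_gggs(
    numbering: ReferenceNumbering,
    query: str,
    anchors: AnchorMap = ANCHORS,
    tolerance: int = 1,
) -> bool:
    """Check the pyrophosphate-binding motif at reference 138-141.

    Allows up to ``tolerance`` mismatches against the GGGS consensus; any
    unmapped motif position counts as a mismatch.
    """
    start, end = anchors.coenzyme_motif
    consensus = anchors.coenzyme_motif_consensus
    mismatches = 0
    for offset, pos in enumerate(range(start, end + 1)):
        if numbering.residue_at_ref(query, pos) != consensus[offset]:
            mismatches += 1
    return mismatches <= tolerance


def detect_hot_inserts(
    numbering: ReferenceNumbering,
    anchors: AnchorMap = ANCHORS,
    minima: tuple[int, int] = HOT_INSERT_MINIMA,
) -> tuple[int, int, bool]:
    """Count query residues aligned inside the two HOT insert spans.

    Returns ``(insert1_len, insert2_len, hot_like)`` where ``hot_like``
    requires both counts to reach their configured minima — HOT proteins
    carry both insertions, other FeADHs neither.
    """

    def span_count(span: Span) -> int:
        return sum(1 for pos in range(span[0], span[1] + 1) if pos in numbering.ref_to_query)

    len1 = span_count(anchors.hot_insert1)
    len2 = span_count(anchors.hot_insert2)
    return len1, len2, (len1 >= minima[0] and len2 >= minima[1])


def _mapped_span(numbering: ReferenceNumbering, span: Span) -> Span | None:
    """Query-coordinate extent of a reference span, or None if unmapped."""
    mapped = [
        numbering.ref_to_query[pos]
        for pos in range(span[0], span[1] + 1)
        if pos in numbering.ref_to_query
    ]
    if not mapped:
        return None
    return (min(mapped), max(mapped))


def annotate(
    record: ProteinRecord,
    reference: ProteinRecord,
    anchors: AnchorMap = ANCHORS,
    config: AlignConfig = DEFAULT_CONFIG,
    gggs_tolerance: int = 1,
    insert_minima: tuple[int, int] = HOT_INSERT_MINIMA,
) -> AnnotationResult:
    """Run every diagnostic rule on one query against the anchored reference.

    Pure function of its inputs: the same (sequence, reference, config)
    triple always yields an identical result.
    """
    numbering = map_to_reference(record, reference, config)
    query = record.residues
    res81 = numbering.residue_at_ref(query, anchors.coenzyme_determinant)
    tetrad = tuple(numbering.residue_at_ref(query, p) for p in anchors.metal_tetrad)
    res334 = numbering.residue_at_ref(query, anchors.catalytic_pos)
    ins1, ins2, hot_like = detect_hot_inserts(numbering, anchors, insert_minima)
    return AnnotationResult(
        query_id=record.id,
        res81=res81,
        coenzyme_call=call_coenzyme(res81),
        tetrad=tetrad,  # type: ignore[arg-type]
        metal_call=call_metal(tetrad),
        gggs_present=detect_gggs(numbering, query, anchors, gggs_tolerance),
        res334=res334,
        insert1_len=ins1,
        insert2_len=ins2,
        hot_like=hot_like,
        gdh_like=flag_gdh_like(tetrad),
        nterm_span=_mapped_span(numbering, anchors.nterm_domain),
        cterm_span=_mapped_span(numbering, anchors.cterm_domain),
        coverage=numbering.coverage,
        low_confidence=numbering.low_confidence,
    )
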