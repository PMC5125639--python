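"""Registry of FeADH subfamilies and diagnostic coordinates.

The iron-containing (type-III) alcohol dehydrogenase family (CDD cd08551)
comprises 19 subfamilies with distinct catalytic activities and a patchy
phyletic distribution across the three domains of life.  This module ships a
machine-readable transcription of that census — per-subfamily presence flags,
eukaryote lineages and diagnostic-residue expectations — together with the
anchor coordinates every functional rule uses, expressed in human ADHFE1
numbering (1-based, reference length 467):

* position 81 — coenzyme-specificity determinant (Asp/Thr vs Gly),
* positions 138-141 — the GGGS pyrophosphate-binding loop,
* positions 242/246/330/357 — the divalent-metal coordination tetrad,
* position 334 — catalytic (substrate-interacting) position,
* spans 256-274 and 342-354 — the two HOT-diagnostic insertions,
* spans 1-229 / 230-467 — Rossmann (coenzyme) and all-helical (metal) domains.

Everything downstream (annotation rules, classification, the synthetic-data
generator) treats this module as the single source of truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "Span",
    "SubfamilyDefinition",
    "AnchorMap",
    "ANCHORS",
    "RegistryError",
    "load_registry",
    "registry_by_id",
    "count_eukaryote_subfamilies",
    "count_tridomain_subfamilies",
    "span_length",
]

#: Valid values for a subfamily's expected metal-site state.
METAL_SITE_STATES = ("tetrad_intact", "asp242_substituted", "variable")

Span = tuple[int, int]


class RegistryError(ValueError):
    """Raised when the packaged registry fails validation."""


@dataclass(frozen=True)
class SubfamilyDefinition:
    """One row of the FeADH subfamily census."""

    cdd_id: str
    abbreviation: str
    activity_note: str
    in_bacteria: bool
    in_eukarya: bool
    in_archaea: bool
    eukaryote_lineages: tuple[str, ...]
    expected_res81: frozenset[str]
    expected_metal_site: str
    footnotes: tuple[str, ...] = field(default=())

    @property
    def tridomain(self) -> bool:
        """True when the subfamily is present in all three domains of life."""
        return self.in_bacteria and self.in_eukarya and self.in_archaea


@dataclass(frozen=True)
class AnchorMap:
    """Diagnostic coordinates in ADHFE1 numbering (1-based, inclusive)."""

    coenzyme_determinant: int = 81
    coenzyme_motif: Span = (138, 141)
    coenzyme_motif_consensus: str = "GGGS"
    metal_tetrad: tuple[int, int, int, int] = (242, 246, 330, 357)
    metal_tetrad_canonical: tuple[str, str, str, str] = ("D", "H", "H", "H")
    catalytic_pos: int = 334
    hot_insert1: Span = (256, 274)
    hot_insert2: Span = (342, 354)
    nterm_domain: Span = (1, 229)
    cterm_domain: Span = (230, 467)
    reference_length: int = 467

    def validate(self) -> None:
        spans = (
            self.coenzyme_motif,
            self.hot_insert1,
            self.hot_insert2,
            self.nterm_domain,
            self.cterm_domain,
        )
        for span in spans:
            if span[0] > span[1]:
                raise RegistryError(f"reversed span {span}")
            if span[0] < 1 or span[1] > self.reference_length:
                raise RegistryError(f"span {span} outside reference")
        positions = (self.coenzyme_determinant, self.catalytic_pos, *self.metal_tetrad)
        for pos in positions:
            if not 1 <= pos <= self.reference_length:
                raise RegistryError(f"position {pos} outside reference")
        if len(self.metal_tetrad) != 4:
            raise RegistryError("metal tetrad must have exactly 4 positions")


#: The family-wide anchor coordinates, validated at import time.
ANCHORS = AnchorMap()
ANCHORS.validate()


def span_length(span: Span) -> int:
    """Length of a 1-based inclusive span: ``end - start + 1``.

    >>> span_length((256, 274))
    19
    """
    start, end = span
    if start > end:
        raise ValueError(f"reversed span ({start}, {end})")
    return end - start + 1


def _parse_row(row: dict) -> SubfamilyDefinition:
    metal = row["expected_metal_site"]
    if metal not in METAL_SITE_STATES:
        raise RegistryError(f"{row['cdd_id']}: unknown metal-site state {metal!r}")
    return SubfamilyDefinition(
        cdd_id=row["cdd_id"],
        abbreviation=row["abbreviation"],
        activity_note=row["activity_note"],
        in_bacteria=bool(row["in_bacteria"]),
        in_eukarya=bool(row["in_eukarya"]),
        in_archaea=bool(row["in_archaea"]),
        eukaryote_lineages=tuple(row["eukaryote_lineages"]),
        expected_res81=frozenset(row["expected_res81"]),
        expected_metal_site=metal,
        footnotes=tuple(row.get("footnotes", ())),
    )


def load_registry() -> list[SubfamilyDefinition]:
    """Load all subfamily definitions, sorted by CDD accession.

    Raises :class:`RegistryError` naming the offending entry when the packaged
    table is corrupt (duplicate accession, lineage/flag mismatch, bad state).
    """
    raw = json.loads(
        resources.files("feadh.data").joinpath("subfamilies.json").read_text()
    )
    defs = [_parse_row(row) for row in raw["subfamilies"]]
    seen: set[str] = set()
    for d in defs:
        if d.cdd_id in seen:
            raise RegistryError(f"duplicate registry entry {d.cdd_id}")
        seen.add(d.cdd_id)
        if d.in_eukarya != bool(d.eukaryote_lineages):
            raise RegistryError(
                f"{d.cdd_id}: eukaryote lineages inconsistent with in_eukarya flag"
            )
    return sorted(defs, key=lambda d: d.cdd_id)


def registry_by_id(
    registry: Iterable[SubfamilyDefinition] | None = None,
) -> dict[str, SubfamilyDefinition]:
    """Index a registry (default: the packaged one) by CDD accession."""
    if registry is None:
        registry = load_registry()
    return {d.cdd_id: d for d in registry}


def count_eukaryote_subfamilies(registry: Iterable[SubfamilyDefinition]) -> int:
    """Number of subfamilies with eukaryotic members."""
    return sum(1 for d in registry if d.in_eukarya)


def count_tridomain_subfamilies(registry: Iterable[SubfamilyDefinition]) -> int:
    """Number of subfamilies present in bacteria, eukarya and archaea."""
    return sum(1 for d in registry if d.tridomain)
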