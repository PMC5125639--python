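"""Subfamily assignment by seed-profile scoring with reciprocal-best-hit checks.

Each of the 19 FeADH subfamilies is represented by a small seed set of member
sequences.  A query is scored against every seed set (mean of the top-k
global-alignment scores), assigned to the best-scoring subfamily when the
margin over the runner-up is large enough AND the reciprocal-best-hit (RBH)
criterion confirms orthology, and otherwise reported as a divergent
singleton.  Sequences whose metal site marks them as glycerol-dehydrogenase
relatives are refused outright — they fall outside the bona fide FeADH
family.

The RBH criterion operationalizes the classic orthology check with the
module's own alignment scores: let s* be the query's best seed; the hit is
reciprocal when s*'s best partner in the pooled set ({query} plus all other
seeds) is either the query itself or a seed of s*'s own subfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignio import (
    AlignConfig,
    DEFAULT_CONFIG,
    EUKARYOTE_GROUPS,
    ProteinRecord,
    align_score,
)
from .annotate import AnnotationResult

__all__ = [
    "SubfamilySeedSet",
    "ClassificationResult",
    "SeedScorer",
    "score_against_seeds",
    "reciprocal_best_hit",
    "assign",
    "classify_records",
    "PhyleticTable",
    "summarize_phyletic",
    "exact_percent",
    "truncated_percent",
]

MIN_SEEDS = 3

STATUS_ASSIGNED = "assigned"
STATUS_DIVERGENT = "divergent_unassigned"
STATUS_EXCLUDED = "excluded_gdh_like"


@dataclass(frozen=True)
class SubfamilySeedSet:
    """Representative member sequences of one subfamily."""

    cdd_id: str
    seeds: tuple[ProteinRecord, ...]
    consensus: str | None = None

    def __post_init__(self) -> None:
        if len(self.seeds) < MIN_SEEDS:
            raise ValueError(
                f"{self.cdd_id}: need at least {MIN_SEEDS} seeds, got {len(self.seeds)}"
            )


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    best_subfamily: str | None
    best_score: float
    second_score: float
    margin: float
    rbh_confirmed: bool
    status: str


def _as_seed_sets(
    seed_sets: Mapping[str, Sequence[ProteinRecord]] | Iterable[SubfamilySeedSet],
) -> list[SubfamilySeedSet]:
    if isinstance(seed_sets, Mapping):
        return [
            SubfamilySeedSet(cdd_id=k, seeds=tuple(v)) for k, v in sorted(seed_sets.items())
        ]
    return sorted(seed_sets, key=lambda s: s.cdd_id)


class SeedScorer:
    """Scores queries against all seed sets, caching seed-vs-seed alignments.

    The cache makes the RBH check O(1) per query: the best partner of any
    seed within the seed pool is precomputed, so only the query-vs-seed
    scores (already needed for classification) are new work.
    """

    def __init__(
        self,
        seed_sets: Mapping[str, Sequence[ProteinRecord]] | Iterable[SubfamilySeedSet],
        config: AlignConfig = DEFAULT_CONFIG,
        top_k: int = 3,
        min_margin_frac: float = 0.05,
    ):
        self.seed_sets = _as_seed_sets(seed_sets)
        self.config = config
        self.top_k = top_k
        self.min_margin_frac = min_margin_frac
        self._seeds: list[tuple[str, ProteinRecord]] = [
            (ss.cdd_id, seed) for ss in self.seed_sets for seed in ss.seeds
        ]
        ids = [seed.id for _, seed in self._seeds]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate seed ids across seed sets")
        self._subfamily_of = {seed.id: cdd for cdd, seed in self._seeds}
        self._best_partner: dict[str, tuple[str, float]] | None = None

    # -- seed-vs-seed cache -------------------------------------------------

    def _ensure_cache(self) -> None:
        if self._best_partner is not None:
            return
        n = len(self._seeds)
        scores = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = align_score(
                    self._seeds[i][1].residues, self._seeds[j][1].residues, self.config
                )
                scores[i, j] = scores[j, i] = s
        self._best_partner = {}
        for i, (_, seed) in enumerate(self._seeds):
            masked = scores[i].copy()
            masked[i] = -np.inf
            j = int(np.argmax(masked))
            self._best_partner[seed.id] = (self._seeds[j][1].id, float(masked[j]))

    # -- scoring ------------------------------------------------------------

    def query_scores(self, query: ProteinRecord) -> dict[str, float]:
        """Alignment score of the query against every individual seed."""
        return {
            seed.id: align_score(query.residues, seed.residues, self.config)
            for _, seed in self._seeds
        }

    def subfamily_scores(self, per_seed: Mapping[str, float]) -> dict[str, float]:
        """Mean of the top-k per-seed scores within each subfamily."""
        out: dict[str, float] = {}
        for ss in self.seed_sets:
            vals = sorted((per_seed[s.id] for s in ss.seeds), reverse=True)
            k = min(self.top_k, len(vals))
            out[ss.cdd_id] = float(np.mean(vals[:k]))
        return out

    def reciprocal_best_hit(
        self, query: ProteinRecord, per_seed: Mapping[str, float]
    ) -> bool:
        self._ensure_cache()
        assert self._best_partner is not None
        best_seed_id = max(per_seed, key=lambda sid: (per_seed[sid], sid))
        partner_id, partner_score = self._best_partner[best_seed_id]
        query_score = per_seed[best_seed_id]
        if query_score >= partner_score:
            return True  # the query itself is s*'s best partner
        return self._subfamily_of[partner_id] == self._subfamily_of[best_seed_id]

    def assign(
        self,
        query: ProteinRecord,
        annotation: AnnotationResult | None = None,
        per_seed: Mapping[str, float] | None = None,
    ) -> ClassificationResult:
        """Classify one query; GDH-like annotations are refused."""
        if annotation is not None and annotation.gdh_like:
            return ClassificationResult(
                query_id=query.id,
                best_subfamily=None,
                best_score=float("nan"),
                second_score=float("nan"),
                margin=float("nan"),
                rbh_confirmed=False,
                status=STATUS_EXCLUDED,
            )
        if per_seed is None:
            per_seed = self.query_scores(query)
        by_subfamily = self.subfamily_scores(per_seed)
        ranked = sorted(by_subfamily.items(), key=lambda kv: (-kv[1], kv[0]))
        best_id, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else float("-inf")
        margin = best - second
        rbh = self.reciprocal_best_hit(query, per_seed)
        min_margin = self.min_margin_frac * abs(best)
        assigned = rbh and margin >= min_margin and margin > 0
        return ClassificationResult(
            query_id=query.id,
            best_subfamily=best_id,
            best_score=best,
            second_score=second,
            margin=margin,
            rbh_confirmed=rbh,
            status=STATUS_ASSIGNED if assigned else STATUS_DIVERGENT,
        )


# -- module-level operations ----------------------------------------------


def score_against_seeds(
    query: ProteinRecord,
    seed_set: SubfamilySeedSet,
    config: AlignConfig = DEFAULT_CONFIG,
    top_k: int = 3,
) -> float:
    """Mean of the top-k alignment scores between query and a seed set."""
    vals = sorted(
        (align_score(query.residues, s.residues, config) for s in seed_set.seeds),
        reverse=True,
    )
    return float(np.mean(vals[: min(top_k, len(vals))]))


def reciprocal_best_hit(
    query: ProteinRecord,
    seed_sets: Mapping[str, Sequence[ProteinRecord]] | Iterable[SubfamilySeedSet],
    config: AlignConfig = DEFAULT_CONFIG,
) -> bool:
    """One-shot RBH check (builds a throwaway scorer; prefer SeedScorer in bulk)."""
    scorer = SeedScorer(seed_sets, config)
    return scorer.reciprocal_best_hit(query, scorer.query_scores(query))


def assign(
    query: ProteinRecord,
    seed_sets: Mapping[str, Sequence[ProteinRecord]] | Iterable[SubfamilySeedSet],
    annotation: AnnotationResult | None = None,
    config: AlignConfig = DEFAULT_CONFIG,
    top_k: int = 3,
    min_margin_frac: float = 0.05,
) -> ClassificationResult:
    """One-shot classification of a single query."""
    scorer = SeedScorer(seed_sets, config, top_k, min_margin_frac)
    return scorer.assign(query, annotation)


def classify_records(
    records: Sequence[ProteinRecord],
    scorer: SeedScorer,
    annotations: Mapping[str, AnnotationResult] | None = None,
) -> list[ClassificationResult]:
    """Classify a batch of queries; order of the input does not affect results."""
    out = []
    for rec in records:
        ann = annotations.get(rec.id) if annotations is not None else None
        out.append(scorer.assign(rec, ann))
    return out


# -- phyletic summary -------------------------------------------------------


def exact_percent(count: int, total: int) -> float:
    """Percentage at one decimal; 0 for an empty total."""
    return round(100.0 * count / total, 1) if total else 0.0


def truncated_percent(count: int, total: int) -> int:
    """Percentage truncated toward zero, e.g. 656/868 -> 75."""
    return int(100.0 * count / total) if total else 0


@dataclass(frozen=True)
class PhyleticTable:
    """Counts of assigned sequences per (taxon group x subfamily)."""

    counts: pd.DataFrame = field(repr=False)  # index: taxon_group, cols: cdd_id

    @property
    def n_assigned(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subfamily_total(self, cdd_id: str) -> int:
        return int(self.counts[cdd_id].sum()) if cdd_id in self.counts else 0

    def group_total(self, group: str) -> int:
        return int(self.counts.loc[group].sum()) if group in self.counts.index else 0

    def eukaryote_share(self, cdd_id: str) -> tuple[float, int]:
        """(exact, truncated) % of eukaryote assignments in one subfamily."""
        euk = [g for g in self.counts.index if g in EUKARYOTE_GROUPS]
        total = int(self.counts.loc[euk].to_numpy().sum())
        count = int(self.counts.loc[euk, cdd_id].sum()) if cdd_id in self.counts else 0
        return exact_percent(count, total), truncated_percent(count, total)

    def group_share(self, group: str, cdd_id: str) -> tuple[float, int]:
        """(exact, truncated) % of one taxon group's assignments in a subfamily."""
        total = self.group_total(group)
        count = (
            int(self.counts.loc[group, cdd_id])
            if group in self.counts.index and cdd_id in self.counts
            else 0
        )
        return exact_percent(count, total), truncated_percent(count, total)


def summarize_phyletic(
    results: Sequence[ClassificationResult],
    records: Sequence[ProteinRecord],
) -> PhyleticTable:
    """Cross-tabulate assigned queries by taxon group and subfamily.

    Only ``assigned`` results enter the table; divergent and excluded
    sequences are deliberately left out, mirroring how a census counts only
    confidently placed members.
    """
    taxon_of = {rec.id: rec.taxon_group for rec in records}
    rows = [
        {"taxon_group": taxon_of[r.query_id], "subfamily": r.best_subfamily}
        for r in results
        if r.status == STATUS_ASSIGNED and r.best_subfamily is not None
    ]
    if not rows:
        return PhyleticTable(counts=pd.DataFrame())
    df = pd.DataFrame(rows)
    counts = pd.crosstab(df["taxon_group"], df["subfamily"])
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    return PhyleticTable(counts=counts)
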