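"""Per-column conservation: residue frequencies and information content.

The conservation display follows the classic sequence-logo computation: for
a column with observed residue frequencies f_a, the information content is

    R = log2(20) - (H + e_n),   H = -sum_a f_a log2 f_a,

where e_n = (s - 1) / (2 n ln 2) (s = 20 residue types) is the small-sample
correction for a column of n observations, and each residue's letter height
is f_a * R.  Gaps never enter the counts.  The interesting positions for
this family are the coenzyme determinant (81) and the metal tetrad
(242/246/330/357), stratified by subfamily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignio import AMINO_ACIDS
from .phylo import ColumnMatrix

__all__ = [
    "LogoColumn",
    "column_information",
    "logo_for_positions",
    "logo_table",
]

GAP = "-"
N_RESIDUE_TYPES = 20
MAX_BITS = math.log2(N_RESIDUE_TYPES)


@dataclass(frozen=True)
class LogoColumn:
    """Conservation summary of one reference-numbered column."""

    ref_position: int
    counts: Mapping[str, int]
    n: int
    information: float
    heights: Mapping[str, float]

    @property
    def top_residue(self) -> str:
        return max(self.counts, key=lambda a: (self.counts[a], a))


def column_information(
    counts: Mapping[str, int] | Sequence[int],
    small_sample_correction: bool = True,
) -> float:
    """Information content (bits) of a residue-count vector.

    A perfectly conserved column carries log2(20) ~ 4.3219 bits (before
    correction); a uniform column carries 0.  The small-sample term
    e_n = 19 / (2 n ln 2) is subtracted when enabled, and the result is
    floored at 0.
    """
    if isinstance(counts, Mapping):
        values = np.array([counts.get(a, 0) for a in AMINO_ACIDS], dtype=float)
    else:
        values = np.asarray(counts, dtype=float)
        if values.shape != (N_RESIDUE_TYPES,):
            raise ValueError(f"expected {N_RESIDUE_TYPES} counts")
    n = values.sum()
    if n < 1:
        raise ValueError("column has no observations")
    freqs = values / n
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    e_n = (N_RESIDUE_TYPES - 1) / (2.0 * n * math.log(2)) if small_sample_correction else 0.0
    return max(MAX_BITS - (entropy + e_n), 0.0)


def _column(
    ref_position: int,
    residues: Iterable[str],
    small_sample_correction: bool,
) -> LogoColumn | None:
    counts: dict[str, int] = {}
    for ch in residues:
        if ch == GAP or ch == "X":
            continue
        counts[ch] = counts.get(ch, 0) + 1
    n = sum(counts.values())
    if n == 0:
        return None
    info = column_information(counts, small_sample_correction)
    heights = {a: (c / n) * info for a, c in counts.items()}
    return LogoColumn(
        ref_position=ref_position,
        counts=counts,
        n=n,
        information=info,
        heights=heights,
    )


def logo_for_positions(
    matrix: ColumnMatrix,
    positions: Sequence[int],
    small_sample_correction: bool = True,
) -> list[LogoColumn]:
    """Logo columns at selected reference positions of a column matrix.

    Positions that are absent from the matrix, or gapped in every sequence,
    are skipped.  Stratify by subfamily by passing a matrix built from one
    subfamily's records.
    """
    index = {pos: i for i, pos in enumerate(matrix.ref_positions)}
    out: list[LogoColumn] = []
    for pos in positions:
        if pos not in index:
            continue
        col = _column(pos, matrix.chars[:, index[pos]], small_sample_correction)
        if col is not None:
            out.append(col)
    return out


def logo_table(columns: Sequence[LogoColumn]) -> pd.DataFrame:
    """Long-form table of letter heights (one row per position x residue)."""
    rows = [
        {
            "ref_position": col.ref_position,
            "residue": a,
            "count": col.counts[a],
            "frequency": col.counts[a] / col.n,
            "height_bits": height,
            "information_bits": col.information,
            "n": col.n,
        }
        for col in columns
        for a, height in sorted(col.heights.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ref_position",
            "residue",
            "count",
            "frequency",
            "height_bits",
            "information_bits",
            "n",
        ],
    )
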