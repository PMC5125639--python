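"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

The family's subfamily structure is recovered here with the classic
distance pipeline: project every sequence onto reference coordinates to get
a shared column matrix, compute pairwise p-distances (optionally
Poisson-corrected, d = -ln(1 - p)), build an unrooted neighbor-joining tree,
and attach nonparametric bootstrap supports (columns resampled with
replacement, default 500 replicates) to its internal edges.  Monophyly of a
label group is then read off as the support of the bipartition isolating
exactly that group.

Neighbor joining is exact on additive matrices and deterministic here: ties
in the Q-criterion are broken toward the smallest pair of node indices in
the current ordering, and negative branch-length estimates are clamped to
zero (the unclamped value is kept on the node).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignio import (
    AlignConfig,
    DEFAULT_CONFIG,
    ProteinRecord,
    map_to_reference,
)

__all__ = [
    "DistanceMatrix",
    "Clade",
    "PhyloTree",
    "ColumnMatrix",
    "pairwise_distances",
    "reference_column_matrix",
    "column_distances",
    "nj_tree",
    "bootstrap_support",
    "monophyly_support",
    "write_newick",
    "read_newick",
]

GAP = "-"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


@dataclass
class Clade:
    """A node of an (un)rooted tree; leaves carry names."""

    name: str | None = None
    branch_length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)
    unclamped_length: float | None = None  # set when NJ estimated < 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out: list[Clade] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves() if l.name is not None)


@dataclass
class PhyloTree:
    """Unrooted tree (root is an arbitrary internal multifurcation)."""

    root: Clade

    @property
    def labels(self) -> frozenset[str]:
        return self.root.leaf_names()

    def total_length(self) -> float:
        total = 0.0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                total += c.branch_length
                stack.append(c)
        return total

    def bipartitions(self) -> dict[frozenset[str], Clade]:
        """Internal-edge bipartitions, keyed by the smaller-side leaf set.

        Each internal edge splits the leaves in two; the key is the side
        listed under the child node, normalized so that a bipartition and
        its complement map to the same key.
        """
        all_leaves = self.labels
        out: dict[frozenset[str], Clade] = {}
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            if node.is_leaf:
                continue
            side = node.leaf_names()
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue  # trivial split
            key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
            out[frozenset(key)] = node
        return out


# -- distances --------------------------------------------------------------


def _shared_column_distance(a: str, b: str) -> float:
    shared = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not shared:
        return 1.0
    diff = sum(1 for x, y in shared if x != y)
    return diff / len(shared)


def _correct(p: float, model: str, max_distance: float) -> float:
    if model == "p":
        return p
    if model == "poisson":
        if p >= 1.0:
            return max_distance
        return min(-math.log(1.0 - p), max_distance)
    raise ValueError(f"unknown distance model {model!r}")


def pairwise_distances(
    records: Sequence[ProteinRecord],
    model: str = "p",
    config: AlignConfig = DEFAULT_CONFIG,
    max_distance: float = 10.0,
) -> DistanceMatrix:
    """All-vs-all distances from pairwise global alignments.

    p-distance is the fraction of differing residues over columns where both
    sequences have one; the Poisson option corrects for multiple hits with
    d = -ln(1-p), capped at ``max_distance`` when p approaches 1.
    """
    from .alignio import global_align

    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].residues, records[j].residues, config)
            p = _shared_column_distance(aln.aligned_a, aln.aligned_b)
            d[i, j] = d[j, i] = _correct(p, model, max_distance)
    return DistanceMatrix(labels=tuple(r.id for r in records), d=d)


@dataclass(frozen=True)
class ColumnMatrix:
    """Sequences projected onto reference coordinates (rows x columns)."""

    labels: tuple[str, ...]
    ref_positions: tuple[int, ...]
    chars: np.ndarray = field(repr=False)  # dtype '<U1', gaps as '-'


def reference_column_matrix(
    records: Sequence[ProteinRecord],
    reference: ProteinRecord,
    config: AlignConfig = DEFAULT_CONFIG,
    max_gap_frac: float | None = 0.5,
) -> ColumnMatrix:
    """Stack reference-numbered residues of every record into a matrix.

    Each record is aligned to the reference; column j holds the residues
    mapped to reference position j (gap where unmapped).  Columns gappier
    than ``max_gap_frac`` are dropped (pass None to keep all columns).
    """
    n_ref = len(reference)
    rows = []
    for rec in records:
        numbering = map_to_reference(rec, reference, config)
        rows.append(
            [numbering.residue_at_ref(rec.residues, pos) for pos in range(1, n_ref + 1)]
        )
    chars = np.array(rows, dtype="<U1")
    positions = np.arange(1, n_ref + 1)
    if max_gap_frac is not None:
        gap_frac = (chars == GAP).mean(axis=0)
        keep = gap_frac <= max_gap_frac
        chars = chars[:, keep]
        positions = positions[keep]
    return ColumnMatrix(
        labels=tuple(r.id for r in records),
        ref_positions=tuple(int(p) for p in positions),
        chars=chars,
    )


def column_distances(
    matrix: ColumnMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    model: str = "p",
    max_distance: float = 10.0,
) -> DistanceMatrix:
    """Pairwise distances over a fixed column matrix (used by the bootstrap)."""
    if isinstance(matrix, ColumnMatrix):
        chars, labels = matrix.chars, matrix.labels
    else:
        chars = matrix
        if labels is None:
            raise ValueError("labels required with a bare array")
    n = chars.shape[0]
    gaps = chars == GAP
    d = np.zeros((n, n))
    for i in range(n):
        shared = ~gaps[i] & ~gaps[i + 1 :]
        diff = (chars[i] != chars[i + 1 :]) & shared
        counts = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(counts > 0, diff.sum(axis=1) / np.maximum(counts, 1), 1.0)
        for off, pij in enumerate(p):
            val = _correct(float(pij), model, max_distance)
            d[i, i + 1 + off] = d[i + 1 + off, i] = val
    return DistanceMatrix(labels=tuple(labels), d=d)


# -- neighbor joining -------------------------------------------------------


def _clamp(node: Clade, length: float) -> None:
    if length < 0:
        node.unclamped_length = length
        node.branch_length = 0.0
    else:
        node.branch_length = length


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining agglomeration (Saitou-Nei) with deterministic ties.

    Returns an unrooted tree whose root is the final trifurcation (or a
    two-child root for the degenerate 2-leaf input, by convention a single
    edge split at its midpoint).
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    nodes: list[Clade] = [Clade(name=lab) for lab in matrix.labels]
    d = matrix.d.astype(float).copy()

    if n == 2:
        for node in nodes:
            node.branch_length = d[0, 1] / 2.0
        return PhyloTree(root=Clade(children=nodes))

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # np.argmin scans row-major, so the first minimum is the smallest
        # (i, j) pair in the current node ordering
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = Clade(children=[nodes[i], nodes[j]])
        _clamp(nodes[i], li)
        _clamp(nodes[j], lj)
        new_d = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # three remaining nodes: closed-form branch lengths to the central node
    (a, b, c) = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, length in ((a, la), (b, lb), (c, lc)):
        _clamp(node, length)
    return PhyloTree(root=Clade(children=[a, b, c]))


# -- bootstrap --------------------------------------------------------------


def bootstrap_support(
    matrix: ColumnMatrix,
    n_replicates: int = 500,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are drawn with replacement ``n_replicates`` times; each
    replicate's NJ tree votes for the bipartitions it contains, and each
    internal edge of the full-data tree receives the percentage of votes it
    collected.  With ``n_replicates=0`` the tree is returned without
    supports.
    """
    if matrix.chars.shape[1] < 2:
        raise ValueError("need at least 2 columns to bootstrap")
    tree = nj_tree(column_distances(matrix, model=model))
    if n_replicates == 0:
        return tree
    biparts = tree.bipartitions()
    votes = {key: 0 for key in biparts}
    rng = np.random.default_rng(seed)
    n_cols = matrix.chars.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = ColumnMatrix(
            labels=matrix.labels,
            ref_positions=tuple(matrix.ref_positions[i] for i in idx),
            chars=matrix.chars[:, idx],
        )
        rep_tree = nj_tree(column_distances(rep, model=model))
        rep_biparts = rep_tree.bipartitions()
        for key in votes:
            if key in rep_biparts:
                votes[key] += 1
    for key, node in biparts.items():
        node.support = 100.0 * votes[key] / n_replicates
    return tree


def monophyly_support(tree: PhyloTree, label_group: Iterable[str]) -> float | None:
    """Bootstrap support of the edge isolating exactly ``label_group``.

    Returns None when the group is not recovered as a bipartition of the
    tree.  The trivial splits (a single leaf, or all leaves) are monophyletic
    by definition and reported as 100.
    """
    group = frozenset(label_group)
    labels = tree.labels
    if not group <= labels:
        raise ValueError("label_group contains unknown leaves")
    if len(group) in (0, 1, len(labels)):
        return 100.0
    complement = labels - group
    key = frozenset(min(group, complement, key=lambda s: (len(s), sorted(s))))
    node = tree.bipartitions().get(key)
    if node is None:
        return None
    return node.support if node.support is not None else 100.0


# -- Newick I/O -------------------------------------------------------------


def _quote(name: str) -> str:
    if re.search(r"[\s(),:;'\[\]]", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _to_newick(node: Clade, with_length: bool = True) -> str:
    if node.is_leaf:
        label = _quote(node.name or "")
    else:
        inner = ",".join(_to_newick(c, with_length) for c in node.children)
        support = "" if node.support is None else f"{node.support:.10g}"
        label = f"({inner}){support}"
    if with_length:
        label += f":{node.branch_length:.10g}"
    return label


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialize to Newick (supports as internal-node labels)."""
    text = (
        "(" + ",".join(_to_newick(c) for c in tree.root.children) + ");\n"
    )
    Path(path).write_text(text)


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a Newick file written by :func:`write_newick`."""
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise ValueError("missing trailing semicolon")
    pos = 0
    s = text[:-1]

    def parse_clade() -> Clade:
        nonlocal pos
        node = Clade()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = _parse_label()
            if label:
                node.support = float(label)
        else:
            node.name = _parse_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", s[pos:])
            if not m:
                raise ValueError(f"bad branch length at offset {pos}")
            node.branch_length = float(m.group(0))
            pos += m.end()
        return node

    def _parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            m = re.match(r"'((?:[^']|'')*)'", s[pos:])
            if not m:
                raise ValueError(f"unterminated quoted label at offset {pos}")
            pos += m.end()
            return m.group(1).replace("''", "'")
        m = re.match(r"[^\s(),:;]+", s[pos:])
        if not m:
            return ""
        pos += m.end()
        return m.group(0)

    root = parse_clade()
    if pos != len(s):
        raise ValueError(f"trailing characters at offset {pos}")
    return PhyloTree(root=root)
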