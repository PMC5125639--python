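"""Distances, neighbor joining (with oracles), bootstrap and Newick I/O."""

import itertools

import numpy as np
import pytest

from feadh.alignio import ProteinRecord
from feadh.phylo import (
    ColumnMatrix,
    DistanceMatrix,
    bootstrap_support,
    column_distances,
    monophyly_support,
    nj_tree,
    pairwise_distances,
    read_newick,
    reference_column_matrix,
    write_newick,
)


def _additive_matrix(leaf_edges, internal_edges, topology):
    """Distances on a tree given leaf branch lengths and split structure."""
    labels = sorted(leaf_edges)
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            dist = leaf_edges[a] + leaf_edges[b]
            for group, length in internal_edges:
                if (a in group) != (b in group):
                    dist += length
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=tuple(labels), d=d)


class TestDistances:
    def test_identical_pair_zero(self):
        recs = [
            ProteinRecord(id="a", residues="MKWVTFIS"),
            ProteinRecord(id="b", residues="MKWVTFIS"),
        ]
        dm = pairwise_distances(recs)
        assert dm.d[0, 1] == 0.0

    def test_one_of_four_shared_columns(self):
        recs = [
            ProteinRecord(id="a", residues="ACDE"),
            ProteinRecord(id="b", residues="ACDF"),
        ]
        dm = pairwise_distances(recs)
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_poisson_of_zero_is_zero(self):
        recs = [
            ProteinRecord(id="a", residues="ACDE"),
            ProteinRecord(id="b", residues="ACDE"),
        ]
        dm = pairwise_distances(recs, model="poisson")
        assert dm.d[0, 1] == 0.0

    def test_poisson_grows_beyond_p(self):
        recs = [
            ProteinRecord(id="a", residues="ACDE"),
            ProteinRecord(id="b", residues="ACDF"),
        ]
        p = pairwise_distances(recs).d[0, 1]
        poisson = pairwise_distances(recs, model="poisson").d[0, 1]
        assert poisson == pytest.approx(-np.log(1 - p))
        assert poisson > p

    def test_saturated_poisson_capped(self):
        chars = np.array([list("AAAA"), list("CCCC")], dtype="<U1")
        dm = column_distances(chars, labels=("a", "b"), model="poisson", max_distance=5.0)
        assert dm.d[0, 1] == 5.0

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=("a", "b", "c"), d=d))
        lengths = {c.name: c.branch_length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_recovers_additive_four_taxon_split(self):
        dm = _additive_matrix(
            {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4},
            [({"a", "b"}, 0.15)],
            None,
        )
        tree = nj_tree(dm)
        assert frozenset({"a", "b"}) in tree.bipartitions()
        assert tree.total_length() == pytest.approx(0.1 + 0.2 + 0.3 + 0.4 + 0.15)

    @pytest.mark.parametrize(
        "splits",
        [
            [({"a", "b"}, 0.2), ({"a", "b", "c"}, 0.1)],
            [({"a", "e"}, 0.25), ({"c", "d"}, 0.3)],
        ],
    )
    def test_recovers_additive_five_taxon_trees(self, splits):
        dm = _additive_matrix(
            {"a": 0.1, "b": 0.2, "c": 0.15, "d": 0.4, "e": 0.3},
            splits,
            None,
        )
        tree = nj_tree(dm)
        biparts = set(tree.bipartitions())
        for group, _ in splits:
            labels = frozenset(dm.labels)
            key = frozenset(
                min(group, labels - frozenset(group), key=lambda s: (len(s), sorted(s)))
            )
            assert key in biparts
        expected = sum(l for _, l in splits) + 0.1 + 0.2 + 0.15 + 0.4 + 0.3
        assert tree.total_length() == pytest.approx(expected)

    def test_matches_scikit_bio_on_random_matrices(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(5)
        for _ in range(3):
            points = rng.random((6, 8))
            d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
            labels = tuple("abcdef")
            mine = nj_tree(DistanceMatrix(labels=labels, d=d))
            other = sknj(SkDM(d, ids=list(labels)))
            sk_biparts = set()
            alln = frozenset(labels)
            for node in other.non_tips():
                tips = frozenset(t.name for t in node.tips())
                if 2 <= len(tips) <= len(alln) - 2:
                    sk_biparts.add(
                        frozenset(
                            min(tips, alln - tips, key=lambda s: (len(s), sorted(s)))
                        )
                    )
            assert set(mine.bipartitions()) == sk_biparts
            assert mine.total_length() == pytest.approx(
                other.descending_branch_length()
            )

    def test_total_length_invariant_under_leaf_permutation(self):
        rng = np.random.default_rng(11)
        points = rng.random((5, 6))
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        labels = tuple("abcde")
        base = nj_tree(DistanceMatrix(labels=labels, d=d))
        perm = [3, 1, 4, 0, 2]
        d2 = d[np.ix_(perm, perm)]
        labels2 = tuple(labels[i] for i in perm)
        permuted = nj_tree(DistanceMatrix(labels=labels2, d=d2))
        assert base.total_length() == pytest.approx(permuted.total_length())
        assert set(base.bipartitions()) == set(permuted.bipartitions())

    def test_degenerate_equidistant_matrix_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=tuple("abcd"), d=d)
        first = nj_tree(dm)
        second = nj_tree(dm)
        assert set(first.bipartitions()) == set(second.bipartitions())

    def test_two_taxon_convention_and_one_taxon_error(self):
        d = np.array([[0.0, 0.8], [0.8, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=("a", "b"), d=d))
        assert tree.total_length() == pytest.approx(0.8)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=("a",), d=np.zeros((1, 1))))

    def test_negative_estimates_clamped_and_recorded(self):
        # a strongly non-additive matrix provokes negative NJ estimates
        d = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 0.1, 1.0],
                [1.0, 0.1, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(labels=tuple("abcd"), d=d))
        stack = [tree.root]
        clamped = []
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            assert node.branch_length >= 0.0
            if node.unclamped_length is not None:
                clamped.append(node.unclamped_length)
        assert clamped and all(v < 0 for v in clamped)


@pytest.fixture(scope="module")
def column_matrix(dataset):
    # two sequences per subfamily keeps the bootstrap cheap
    keep, seen = [], {}
    for rec, truth in zip(dataset.records, dataset.truths):
        if seen.get(truth.true_subfamily, 0) < 2:
            seen[truth.true_subfamily] = seen.get(truth.true_subfamily, 0) + 1
            keep.append(rec)
    return reference_column_matrix(keep, dataset.reference)


class TestBootstrap:
    def test_same_seed_reproduces_supports(self, column_matrix):
        t1 = bootstrap_support(column_matrix, n_replicates=60, seed=9)
        t2 = bootstrap_support(column_matrix, n_replicates=60, seed=9)
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_subfamily_pairs_strongly_supported(self, dataset, column_matrix):
        tree = bootstrap_support(column_matrix, n_replicates=60, seed=9)
        truth = {t.seq_id: t.true_subfamily for t in dataset.truths}
        by_subfamily = {}
        for name in tree.labels:
            by_subfamily.setdefault(truth[name], []).append(name)
        for cdd, ids in by_subfamily.items():
            support = monophyly_support(tree, ids)
            assert support is not None and support >= 90.0, cdd

    def test_zero_replicates_returns_unsupported_tree(self, column_matrix):
        tree = bootstrap_support(column_matrix, n_replicates=0, seed=1)
        assert all(n.support is None for n in tree.bipartitions().values())

    def test_too_few_columns_rejected(self):
        cm = ColumnMatrix(labels=("a", "b"), ref_positions=(1,),
                          chars=np.array([["A"], ["C"]], dtype="<U1"))
        with pytest.raises(ValueError):
            bootstrap_support(cm, n_replicates=10, seed=0)


class TestMonophyly:
    def test_trivial_groups_are_monophyletic(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=("a", "b", "c"), d=d))
        assert monophyly_support(tree, ["a", "b", "c"]) == 100.0
        assert monophyly_support(tree, ["a"]) == 100.0

    def test_scattered_group_not_recovered(self):
        dm = _additive_matrix(
            {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4},
            [({"a", "b"}, 0.15)],
            None,
        )
        tree = nj_tree(dm)
        assert monophyly_support(tree, ["a", "c"]) is None

    def test_unknown_leaves_rejected(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=("a", "b", "c"), d=d))
        with pytest.raises(ValueError):
            monophyly_support(tree, ["a", "zzz"])


class TestNewick:
    def test_three_taxon_single_line(self, tmp_path):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=("a", "b", "c"), d=d))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text()
        assert text.count("\n") == 1 and text.endswith(";\n")

    def test_round_trip_preserves_topology_lengths_supports(self, tmp_path, dataset):
        keep = dataset.records[:8]
        matrix = reference_column_matrix(keep, dataset.reference)
        tree = bootstrap_support(matrix, n_replicates=20, seed=3)
        path = tmp_path / "boot.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.labels == tree.labels
        assert back.total_length() == pytest.approx(tree.total_length(), abs=1e-9)
        orig = {k: n.support for k, n in tree.bipartitions().items()}
        parsed = {k: n.support for k, n in back.bipartitions().items()}
        assert parsed == orig

    def test_labels_with_spaces_quoted(self, tmp_path):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(
            DistanceMatrix(labels=("taxon a", "taxon b", "c:d"), d=d)
        )
        path = tmp_path / "q.nwk"
        write_newick(tree, path)
        assert "'taxon a'" in path.read_text()
        back = read_newick(path)
        assert back.labels == frozenset({"taxon a", "taxon b", "c:d"})
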