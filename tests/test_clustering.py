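import io
import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from degpath.clustering import (
    agglomerate,
    correlation_distance,
    hierarchical_order,
    ordered_matrix,
    to_newick,
)
from degpath.diffexpr import DegPartition
from degpath.errors import ValidationError

from conftest import make_log2_matrix


def naive_average_linkage(dist):
    """Brute-force O(k^3) agglomeration oracle: recompute every cluster-pair
    distance as the mean over all leaf pairs at each step."""
    k = dist.shape[0]
    clusters = {i: [i] for i in range(k)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            key = (d, min(min(clusters[a]), min(clusters[b])),
                   max(min(clusters[a]), min(clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((min(clusters[a]), min(clusters[b]), d))
        clusters[min(a, b)] = clusters[a] + clusters[b]
        del clusters[max(a, b)]
    return merges


class TestCorrelationDistance:
    def test_identical_rows_have_zero_distance(self):
        d = correlation_distance(np.array([[1.0, 2, 3], [1.0, 2, 3], [3, 1, 2]]))
        assert d[0, 1] == 0.0

    def test_perfect_anticorrelation_is_two(self):
        d = correlation_distance(np.array([[1.0, 2, 3], [3.0, 2, 1]]))
        assert np.isclose(d[0, 1], 2.0)

    def test_matches_per_pair_pearson(self, rng):
        x = rng.normal(0, 1, size=(5, 4))
        d = correlation_distance(x)
        for i in range(5):
            for j in range(5):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert np.isclose(d[i, j], 1 - r, atol=1e-12)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_zero_variance_row_named(self):
        with pytest.raises(ValidationError, match="row 1"):
            correlation_distance(np.array([[1.0, 2, 3], [5.0, 5, 5]]))


class TestAgglomerate:
    def test_identical_pair_merges_first_at_height_zero(self, rng):
        x = rng.normal(0, 1, size=(3, 5))
        x[2] = x[0]  # rows 0 and 2 identical
        _, merges = agglomerate(correlation_distance(x))
        assert merges[0] == (0, 2, 0.0)

    def test_matches_naive_oracle_on_random_fixture(self, rng):
        x = rng.normal(0, 1, size=(6, 5))
        d = correlation_distance(x)
        _, merges = agglomerate(d)
        expected = naive_average_linkage(d)
        for (a, b, h), (ea, eb, eh) in zip(merges, expected):
            assert {a, b} == {ea, eb}
            assert np.isclose(h, eh, atol=1e-12)

    def test_matches_scipy_heights_on_tie_free_data(self, rng):
        x = rng.normal(0, 1, size=(12, 6))
        d = correlation_distance(x)
        _, merges = agglomerate(d)
        Z = scipy_linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(sorted(h for _, _, h in merges),
                                   np.sort(Z[:, 2]), atol=1e-10)

    def test_heights_non_decreasing(self, rng):
        x = rng.normal(0, 1, size=(15, 5))
        _, merges = agglomerate(correlation_distance(x))
        heights = [h for _, _, h in merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_permutation_invariance_of_topology_and_heights(self, rng):
        x = rng.normal(0, 1, size=(8, 5))
        d = correlation_distance(x)
        perm = rng.permutation(8)
        dp = d[np.ix_(perm, perm)]
        _, merges = agglomerate(d)
        _, merges_p = agglomerate(dp)
        # merge labels are cluster-min indices, which the permutation relabels;
        # the tree itself is permutation-invariant, so the height sequences of
        # the agglomeration match exactly step by step
        assert [round(h, 10) for _, _, h in merges_p] == \
               [round(h, 10) for _, _, h in merges]


class TestHierarchicalOrder:
    def _fixture(self, rng, k=10, s=6):
        vals = rng.normal(0, 1, size=(k, s))
        genes = [f"G{i:02d}" for i in range(k)]
        m = make_log2_matrix(vals, genes=genes)
        part = DegPartition(up=tuple(genes[:3]), down=tuple(genes[3:]), alpha=0.05)
        return m, part

    def test_order_is_permutation_of_degs(self, rng):
        m, part = self._fixture(rng)
        ordering = hierarchical_order(m, part)
        assert sorted(ordering.gene_order) == sorted(part.up + part.down)
        assert sorted(ordering.sample_order) == sorted(m.sample_ids)

    def test_order_consistent_with_tree_traversal(self, rng):
        m, part = self._fixture(rng)
        ordering = hierarchical_order(m, part)
        deg_ids = list(part.down) + list(part.up)
        assert list(ordering.gene_order) == [
            deg_ids[i] for i in ordering.gene_tree.leaves()]

    def test_merged_pairs_are_contiguous(self, rng):
        m, part = self._fixture(rng)
        ordering = hierarchical_order(m, part)
        # every subtree's leaves occupy a contiguous block of the ordering
        def check(node):
            if node.leaf is not None:
                return
            leaves = node.leaves()
            pos = [ordering.gene_tree.leaves().index(l) for l in leaves]
            assert max(pos) - min(pos) + 1 == len(pos)
            check(node.left)
            check(node.right)
        check(ordering.gene_tree)

    def test_single_deg_is_trivial(self, rng):
        m, _ = self._fixture(rng)
        part = DegPartition(up=("G00",), down=(), alpha=0.05)
        ordering = hierarchical_order(m, part)
        assert ordering.gene_order == ("G00",)
        assert ordering.gene_tree is None

    def test_newick_round_trips_through_dendropy(self, rng):
        import dendropy

        m, part = self._fixture(rng)
        ordering = hierarchical_order(m, part)
        deg_ids = list(part.down) + list(part.up)
        nwk = to_newick(ordering.gene_tree, deg_ids)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(deg_ids)
        # ultrametric: root-to-leaf path length equals the root merge height
        root_height = ordering.gene_tree.height
        for leaf in tree.leaf_node_iter():
            assert np.isclose(leaf.distance_from_root(), root_height, atol=1e-8)

    def test_ordered_matrix_applies_permutation(self, rng):
        m, part = self._fixture(rng)
        ordering = hierarchical_order(m, part)
        out = ordered_matrix(m, ordering)
        assert list(out.index) == list(ordering.gene_order)
        assert list(out.columns) == list(ordering.sample_order)
        assert np.array_equal(
            out.to_numpy(),
            m.values.loc[list(ordering.gene_order),
                         list(ordering.sample_order)].to_numpy())
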