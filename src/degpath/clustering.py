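"""Hierarchical clustering of DEG expression profiles for heatmap ordering.

Genes (and samples) are clustered agglomeratively on correlation distance
d(i, j) = 1 - Pearson(i, j) with average linkage — the defaults of the
array-era heatmap tools. The agglomeration is implemented here rather than
delegated because the ordering contract is fully deterministic:

* among equidistant pairs, the pair containing the lowest original row index
  merges first;
* at every merge the subtree whose minimal original index is smaller becomes
  the left child, so the leaf order needs no optimal-leaf-ordering pass.

The result is the row/column permutation behind a clustered heatmap plus the
merge trees, exportable as Newick with branch lengths equal to merge-height
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DegPartition
from .errors import ValidationError
from .matrix_io import LOG2_CENTERED, ExpressionMatrix

__all__ = [
    "ClusterNode",
    "ClusterOrdering",
    "correlation_distance",
    "euclidean_distance",
    "agglomerate",
    "hierarchical_order",
    "to_newick",
    "ordered_matrix",
]

CORRELATION = "correlation"
EUCLIDEAN = "euclidean"
AVERAGE = "average"
COMPLETE = "complete"


@dataclass(frozen=True)
class ClusterNode:
    """A node of the merge tree; leaves carry the original row index."""

    height: float
    min_index: int  # smallest original leaf index under this node
    size: int
    leaf: int | None = None
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None

    def leaves(self) -> list[int]:
        """Depth-first leaf indices (left first)."""
        if self.leaf is not None:
            return [self.leaf]
        return self.left.leaves() + self.right.leaves()


@dataclass(frozen=True)
class ClusterOrdering:
    """Deterministic row/column ordering with the underlying merge trees."""

    gene_order: tuple[str, ...]
    sample_order: tuple[str, ...]
    gene_tree: ClusterNode | None
    sample_tree: ClusterNode | None
    gene_merges: tuple[tuple[int, int, float], ...]
    sample_merges: tuple[tuple[int, int, float], ...]


def correlation_distance(profiles) -> np.ndarray:
    """Pairwise 1 - Pearson distance matrix for the rows of ``profiles``.

    Symmetric, zero diagonal, range [0, 2] (2 = perfect anticorrelation).
    Rows with zero variance have no defined correlation and are rejected.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValidationError(f"row {bad} has zero variance; correlation undefined")
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize against fp noise
    return d


def euclidean_distance(profiles) -> np.ndarray:
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    sq = (x[:, None, :] - x[None, :, :]) ** 2
    return np.sqrt(sq.sum(axis=-1))


def agglomerate(dist: np.ndarray, linkage: str = AVERAGE,
                ) -> tuple[ClusterNode, list[tuple[int, int, float]]]:
    """Agglomerative clustering of a square distance matrix.

    Lance–Williams updates (average: size-weighted mean; complete: max).
    Tie-break on equal merge distances: the pair whose smallest original
    member index is lowest wins, then the other side's smallest index.
    Returns the root node and the merge list [(min_index_a, min_index_b,
    height), ...] in agglomeration order.
    """
    if linkage not in (AVERAGE, COMPLETE):
        raise ValidationError(f"unknown linkage {linkage!r}")
    k = dist.shape[0]
    if dist.shape != (k, k):
        raise ValidationError("distance matrix must be square")
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(height=0.0, min_index=i, size=1, leaf=i) for i in range(k)
    }
    active = list(range(k))
    merges: list[tuple[int, int, float]] = []
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        dmin = sub.min()
        pairs = [
            (nodes[active[i]].min_index, nodes[active[j]].min_index,
             active[i], active[j])
            for i, j in zip(*np.nonzero(sub == dmin)) if i < j
        ]
        # lowest original index merges first
        _, _, a, b = min(pairs, key=lambda t: (min(t[0], t[1]), max(t[0], t[1])))
        na, nb = nodes[a], nodes[b]
        left, right = (na, nb) if na.min_index <= nb.min_index else (nb, na)
        parent = ClusterNode(height=float(dmin), min_index=left.min_index,
                             size=na.size + nb.size, left=left, right=right)
        merges.append((left.min_index, right.min_index, float(dmin)))
        # Lance-Williams update into slot a; retire slot b
        others = [x for x in active if x not in (a, b)]
        if others:
            if linkage == AVERAGE:
                upd = (na.size * d[a, others] + nb.size * d[b, others]) / (na.size + nb.size)
            else:
                upd = np.maximum(d[a, others], d[b, others])
            d[a, others] = upd
            d[others, a] = upd
        d[b, :] = np.inf
        d[:, b] = np.inf
        nodes[a] = parent
        del nodes[b]
        active.remove(b)
    return nodes[active[0]], merges


_METRICS = {CORRELATION: correlation_distance, EUCLIDEAN: euclidean_distance}


def hierarchical_order(m: ExpressionMatrix, degs: DegPartition,
                       metric: str = CORRELATION, linkage: str = AVERAGE,
                       ) -> ClusterOrdering:
    """Cluster the DEG rows and the samples of a normalized matrix.

    Gene profiles are the DEG rows (down list then up list, in their
    partition order, which fixes the original indices); sample profiles are
    the columns of that DEG submatrix. A single DEG yields the trivial
    ordering with no tree.
    """
    if m.scale != LOG2_CENTERED:
        raise ValidationError("hierarchical_order expects a normalized matrix")
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    deg_ids = list(degs.down) + list(degs.up)
    if not deg_ids:
        raise ValidationError("DEG list is empty; nothing to cluster")
    sub = m.values.loc[deg_ids]
    samples = list(sub.columns)

    if len(deg_ids) == 1:
        return ClusterOrdering(tuple(deg_ids), tuple(samples), None, None, (), ())

    gene_tree, gene_merges = agglomerate(_METRICS[metric](sub.to_numpy()), linkage)
    sample_tree, sample_merges = agglomerate(
        _METRICS[metric](sub.to_numpy().T), linkage)
    return ClusterOrdering(
        gene_order=tuple(deg_ids[i] for i in gene_tree.leaves()),
        sample_order=tuple(samples[i] for i in sample_tree.leaves()),
        gene_tree=gene_tree,
        sample_tree=sample_tree,
        gene_merges=tuple(gene_merges),
        sample_merges=tuple(sample_merges),
    )


def to_newick(tree: ClusterNode, labels) -> str:
    """Newick string with branch lengths = parent height − child height."""
    labels = list(labels)

    def render(node: ClusterNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.leaf is not None:
            return f"{labels[node.leaf]}:{length:.10g}"
        inner = f"({render(node.left, node.height)},{render(node.right, node.height)})"
        return f"{inner}:{length:.10g}"

    if tree.leaf is not None:
        return f"({labels[tree.leaf]}:0);"
    return (f"({render(tree.left, tree.height)},"
            f"{render(tree.right, tree.height)});")


def ordered_matrix(m: ExpressionMatrix, ordering: ClusterOrdering) -> pd.DataFrame:
    """The DEG submatrix reordered to the clustered gene/sample permutation."""
    return m.values.loc[list(ordering.gene_order), list(ordering.sample_order)]
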