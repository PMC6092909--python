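"""Client-side style data operations: cross-column aggregation,
pairwise distances and agglomerative hierarchical clustering with
dendrogram output.

The clusterer is authored here (not delegated to scipy) because the
contract pins deterministic lexicographic tie-breaking and a
left-to-right leaf order; tests check it against an independent naive
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ColumnTable, make_column_table

__all__ = [
    "AGGREGATION_STATS",
    "DISTANCE_METRICS",
    "LINKAGES",
    "DendroNode",
    "Dendrogram",
    "aggregate_columns",
    "pairwise_distances",
    "hierarchical_cluster",
]

AGGREGATION_STATS = ("mean", "min", "max", "sum", "median")
DISTANCE_METRICS = ("euclidean", "one_minus_pearson", "manhattan")
LINKAGES = ("single", "complete", "average")


def aggregate_columns(
    table: ColumnTable,
    columns: Sequence[str],
    stat: str,
    out_name: str,
) -> ColumnTable:
    """Add a column ``out_name`` = per-row ``stat`` over ``columns``.

    Nulls are skipped; all-null rows yield null.  Input columns are
    retained.
    """
    if stat not in AGGREGATION_STATS:
        raise ValueError(f"unknown stat {stat!r}; choose from {AGGREGATION_STATS}")
    for c in columns:
        if c not in table.values:
            raise KeyError(f"unknown column {c!r}")
    if out_name in table.values:
        raise ValueError(f"output column {out_name!r} already exists")
    if not columns:
        raise ValueError("need at least one column to aggregate")

    mat = np.vstack([table.values[c] for c in columns])  # columns x rows
    fn = {
        "mean": np.nanmean,
        "min": np.nanmin,
        "max": np.nanmax,
        "sum": np.nansum,
        "median": np.nanmedian,
    }[stat]
    all_null = np.all(np.isnan(mat), axis=0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        agg = fn(mat, axis=0)
    agg = np.where(all_null, np.nan, agg)

    new_values = {name: col.copy() for name, col in table.values.items()}
    new_values[out_name] = agg
    return make_column_table(
        table.chrom, table.start, table.end, new_values, table.row_names
    )


def pairwise_distances(matrix, metric: str = "euclidean") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix between the rows of
    ``matrix``.

    ``one_minus_pearson`` raises on constant rows (correlation is
    undefined there).  Rows containing NaN are mean-imputed per column
    first.
    """
    if metric not in DISTANCE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {DISTANCE_METRICS}")
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if np.any(np.all(np.isnan(x), axis=1)):
        raise ValueError("all-null rows are not clusterable")
    x = _impute_column_means(x)

    if metric == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt(np.sum(diff**2, axis=2))
    elif metric == "manhattan":
        diff = x[:, None, :] - x[None, :, :]
        d = np.sum(np.abs(diff), axis=2)
    else:  # one_minus_pearson
        sd = np.std(x, axis=1)
        if np.any(sd == 0):
            i = int(np.nonzero(sd == 0)[0][0])
            raise ValueError(
                f"row {i} is constant; Pearson correlation is undefined"
            )
        c = np.corrcoef(x)
        d = 1.0 - c
        np.fill_diagonal(d, 0.0)
        d = np.maximum(d, 0.0)
    return (d + d.T) / 2.0  # enforce exact symmetry


def _impute_column_means(x: np.ndarray) -> np.ndarray:
    if not np.any(np.isnan(x)):
        return x
    x = x.copy()
    col_means = np.nanmean(x, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = col_means[nan_c]
    return x


@dataclass(frozen=True)
class DendroNode:
    """A node of the merge tree.

    Leaves have ``height`` 0 and no children; internal nodes carry the
    merge distance.  ``leaf_ids`` caches the left-to-right leaf labels
    under this node.
    """

    id: str
    height: float
    children: tuple = ()  # () for leaves, (left, right) otherwise
    leaf_ids: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree from agglomerative clustering."""

    root: DendroNode
    labels: tuple

    @property
    def leaf_order(self) -> tuple:
        """Leaf labels from a left-to-right traversal."""
        return self.root.leaf_ids

    @property
    def merge_heights(self) -> list[float]:
        """All internal-node heights, sorted ascending."""
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node.height)
                stack.extend(node.children)
        return sorted(out)

    def to_newick(self) -> str:
        """Newick text with branch lengths = parent height - child height."""

        def rec(node: DendroNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.id}:{blen:.10g}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{blen:.10g}"

        left, right = self.root.children
        inner = ",".join(rec(c, self.root.height) for c in (left, right))
        return f"({inner});"

    def to_json_tree(self) -> dict:
        """Nested dict for the renderer: {id, height, children}."""

        def rec(node: DendroNode) -> dict:
            d = {"id": node.id, "height": node.height}
            if node.children:
                d["children"] = [rec(c) for c in node.children]
            return d

        return rec(self.root)


def hierarchical_cluster(
    distances,
    linkage: str = "complete",
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    n-1 merges; inter-cluster distance is min / max / unweighted
    average of all cross pairs for single / complete / average linkage.
    Equal-distance ties merge the lexicographically smallest cluster-id
    pair, so output is deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    d = np.asarray(distances, dtype=np.float64)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")

    # Lance-Williams agglomeration: cluster-to-cluster distances are
    # updated incrementally rather than recomputed from the input
    # matrix (tests check against a direct all-pairs reference).
    clusters: dict[tuple, tuple[DendroNode, int]] = {}  # key -> (node, size)
    for i in range(n):
        node = DendroNode(id=labels[i], height=0.0, leaf_ids=(labels[i],))
        clusters[(labels[i],)] = (node, 1)

    keys = sorted(clusters.keys())
    cdist: dict[frozenset, float] = {}
    label_row = {labels[i]: i for i in range(n)}
    for ai in range(len(keys)):
        for bi in range(ai + 1, len(keys)):
            ka, kb = keys[ai], keys[bi]
            cdist[frozenset((ka, kb))] = float(
                d[label_row[ka[0]], label_row[kb[0]]]
            )

    while len(clusters) > 1:
        keys = sorted(clusters.keys())
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                ka, kb = keys[ai], keys[bi]
                cand = (cdist[frozenset((ka, kb))], ka, kb)
                if best is None or cand < best:
                    best = cand
        dist, ka, kb = best
        node_a, size_a = clusters.pop(ka)
        node_b, size_b = clusters.pop(kb)
        merged_key = tuple(sorted(ka + kb))
        merged = DendroNode(
            id=f"({node_a.id}+{node_b.id})",
            height=dist,
            children=(node_a, node_b),
            leaf_ids=node_a.leaf_ids + node_b.leaf_ids,
        )
        for ko in list(clusters.keys()):
            da = cdist.pop(frozenset((ka, ko)))
            db = cdist.pop(frozenset((kb, ko)))
            if linkage == "single":
                dn = min(da, db)
            elif linkage == "complete":
                dn = max(da, db)
            else:  # average (UPGMA update)
                dn = (size_a * da + size_b * db) / (size_a + size_b)
            cdist[frozenset((merged_key, ko))] = dn
        cdist.pop(frozenset((ka, kb)), None)
        clusters[merged_key] = (merged, size_a + size_b)

    (root, _size), = clusters.values()
    return Dendrogram(root=root, labels=labels)
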