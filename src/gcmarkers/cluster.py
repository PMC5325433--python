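"""Two-way average-linkage hierarchical clustering with Cluster 3.0 conventions.

Distances follow the conventions of the Cluster 3.0 desktop tool used for the
original heat maps: City Block distance as the *mean* absolute difference over
jointly observed components (so values are comparable across missingness
patterns), correlation distance as 1 - Pearson r (an uncentered cosine variant
is available), and UPGMA (size-weighted average linkage) agglomeration.
Expression matrices are log-transformed with base 150 so that the normal
ceiling of the screen maps to 1.0.

Missing entries are allowed throughout and handled pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CITYBLOCK = "cityblock"
CORRELATION = "correlation"


def log150_transform(x):
    """log base 150 of a signal score; scores below 1 are clipped to 0.

    150 is the screen's normal ceiling, so transformed values of 1.0 mark that
    boundary.  Accepts scalars or arrays; negative input is rejected.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("signal scores must be non-negative")
    out = np.log(np.maximum(arr, 1.0)) / np.log(150.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def cityblock_distance(a, b) -> float:
    """Mean absolute difference over jointly observed components.

    Missing entries (NaN) are skipped pairwise; with no overlap the distance
    is undefined and an error is raised.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    if not mask.any():
        raise ValueError("no jointly observed components")
    return float(np.mean(np.abs(a[mask] - b[mask])))


def correlation_distance(a, b, centered: bool = True) -> float:
    """1 - Pearson correlation over jointly observed components.

    With ``centered=False`` the uncentered (cosine) variant is used.  Requires
    at least two joint observations; zero variance (centered) or an all-zero
    vector (uncentered) is rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 2:
        raise ValueError("need >= 2 jointly observed components")
    x, y = a[mask], b[mask]
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        kind = "zero variance" if centered else "zero norm"
        raise ValueError(
            f"correlation distance undefined ({kind}); "
            "drop constant items or use the City Block metric"
        )
    return float(1.0 - (x @ y) / (nx * ny))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a metric tag."""

    values: np.ndarray
    metric: str
    ids: Optional[list] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distances(
    X, metric: str = CITYBLOCK, centered: bool = True, ids: Optional[Sequence] = None
) -> DistanceMatrix:
    """All pairwise distances between the rows of ``X`` (NaN-aware)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == CITYBLOCK:
                d = cityblock_distance(X[i], X[j])
            elif metric == CORRELATION:
                d = correlation_distance(X[i], X[j], centered=centered)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            D[i, j] = D[j, i] = max(d, 0.0)
    return DistanceMatrix(values=D, metric=metric, ids=list(ids) if ids is not None else None)


@dataclass
class Dendrogram:
    """Agglomeration history: (left, right, height, size) per merge.

    Leaves are numbered 0..n-1 in input order; merge i creates cluster n+i.
    The left child of every merge is the earlier-created cluster.  ``leaf_order``
    is the left-to-right leaf sequence of the tree.
    """

    n_leaves: int
    merges: list  # (left_id, right_id, height, merged_size)
    leaf_order: list = field(init=False)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves has n-1 merges")
        heights = [m[2] for m in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("average-linkage merge heights must be non-decreasing")
        self.leaf_order = self._order(self.n_leaves + len(self.merges) - 1) if self.merges else [0]

    def _children(self, node: int) -> tuple[int, int]:
        left, right, _, _ = self.merges[node - self.n_leaves]
        return left, right

    def _order(self, node: int) -> list:
        if node < self.n_leaves:
            return [node]
        left, right = self._children(node)
        return self._order(left) + self._order(right)

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else self.merges[node - self.n_leaves][2]


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of a distance matrix.

    Repeatedly merges the closest active pair; the distance from a merged
    cluster A∪B to any C is the size-weighted mean
    (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|).  Ties are broken by the smallest
    (id, id) pair in cluster-creation order, making the result deterministic.
    """
    n = dist.n
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    D[:n, :n] = dist.values
    np.fill_diagonal(D, np.inf)
    size = np.zeros(total, dtype=int)
    size[:n] = 1
    active = list(range(n))
    merges = []
    for step in range(n - 1):
        best = (np.inf, -1, -1)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if D[i, j] < best[0]:
                    best = (D[i, j], i, j)
        h, i, j = best
        new = n + step
        size[new] = size[i] + size[j]
        for c in active:
            if c in (i, j):
                continue
            D[new, c] = D[c, new] = (size[i] * D[i, c] + size[j] * D[j, c]) / size[new]
        active = [c for c in active if c not in (i, j)] + [new]
        merges.append((i, j, float(h), int(size[new])))
    return Dendrogram(n_leaves=n, merges=merges)


def cut_tree(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels from cutting the tree into ``k`` clusters.

    The k-1 highest merges are removed (merges are height-ordered, so the
    first n-k merges are applied).  Labels are 0..k-1 in order of first
    appearance along the leaf order.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        left, right, _, _ = dendrogram.merges[step]
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new
    labels = np.empty(n, dtype=int)
    seen: dict = {}
    for leaf in dendrogram.leaf_order:
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen)
    for leaf in range(n):
        labels[leaf] = seen[find(leaf)]
    return labels


@dataclass
class TwoWayResult:
    """Row and column dendrograms plus the doubly reordered matrix."""

    row_tree: Dendrogram
    col_tree: Dendrogram
    reordered: pd.DataFrame
    transformed: pd.DataFrame


def two_way_cluster(
    matrix: pd.DataFrame,
    row_metric: str = CITYBLOCK,
    col_metric: str = CORRELATION,
    transform: bool = False,
    centered: bool = True,
) -> TwoWayResult:
    """Cluster rows and columns independently and reorder the matrix by both.

    The default metrics mirror the original analysis: City Block over samples
    (rows) and correlation over markers/antibodies (columns).  With
    ``transform=True`` the log-base-150 transform is applied first
    (expression mode).  Missing entries are allowed; a fully missing row or
    column is rejected by name.
    """
    matrix = pd.DataFrame(matrix)
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    data = matrix.astype(float)
    if transform:
        data = pd.DataFrame(
            log150_transform(data.to_numpy()), index=data.index, columns=data.columns
        )
    all_missing_rows = data.index[data.isna().all(axis=1)]
    if len(all_missing_rows):
        raise ValueError(f"row(s) entirely missing: {list(all_missing_rows)}")
    all_missing_cols = data.columns[data.isna().all(axis=0)]
    if len(all_missing_cols):
        raise ValueError(f"column(s) entirely missing: {list(all_missing_cols)}")
    row_tree = average_linkage(
        pairwise_distances(data.to_numpy(), row_metric, centered, ids=list(data.index))
    )
    col_tree = average_linkage(
        pairwise_distances(data.to_numpy().T, col_metric, centered, ids=list(data.columns))
    )
    reordered = data.iloc[row_tree.leaf_order, col_tree.leaf_order]
    return TwoWayResult(
        row_tree=row_tree, col_tree=col_tree, reordered=reordered, transformed=data
    )


def to_newick(dendrogram: Dendrogram, labels: Optional[Sequence[str]] = None) -> str:
    """Newick string with branch lengths = parent height - child height."""
    n = dendrogram.n_leaves
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("one label per leaf required")

    def render(node: int, parent_height: float) -> str:
        length = parent_height - dendrogram.node_height(node)
        if node < n:
            return f"{labels[node]}:{length:.10g}"
        left, right = dendrogram._children(node)
        h = dendrogram.node_height(node)
        return f"({render(left, h)},{render(right, h)}):{length:.10g}"

    root = n + len(dendrogram.merges) - 1
    root_h = dendrogram.node_height(root)
    left, right = dendrogram._children(root)
    return f"({render(left, root_h)},{render(right, root_h)});"
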