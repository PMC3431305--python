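"""Single-linkage hierarchical clustering of score vectors with cluster metrics.

Dendrograms over the first one or two predictive OPLS-DA score columns
visualize class separation. Each internal node carries two metrics:
*compactness*, the node's merge height (the Euclidean single-linkage
distance at which its members join — distance from 0 on the dendrogram
axis; smaller means chemically more similar members), and
*distinctness*, the height gap from the node to its parent (larger
means the cluster is more separated from its sibling). The root's
distinctness is 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy


@dataclass(frozen=True)
class ClusterMetrics:
    cluster_id: int
    compactness: float
    distinctness: float


class Dendrogram:
    """Single-linkage merge tree over observations.

    Wraps a scipy linkage matrix. Nodes are numbered scipy-style: leaves
    0..n-1, internal nodes n..2n-2 in merge order (non-decreasing height).
    """

    def __init__(self, linkage_matrix: np.ndarray,
                 leaf_labels: list[str] | None = None):
        Z = np.asarray(linkage_matrix, dtype=float)
        n = Z.shape[0] + 1
        if leaf_labels is None:
            leaf_labels = [str(i) for i in range(n)]
        if len(leaf_labels) != n:
            raise ValueError("leaf label count does not match linkage size")
        if np.any(np.diff(Z[:, 2]) < -1e-12):
            raise ValueError("merge heights must be non-decreasing (single linkage)")
        self.Z = Z
        self.leaf_labels = list(leaf_labels)
        self.n_leaves = n
        # parent lookup: node id -> merge row index of its parent
        self._parent_row: dict[int, int] = {}
        for row in range(Z.shape[0]):
            self._parent_row[int(Z[row, 0])] = row
            self._parent_row[int(Z[row, 1])] = row

    def height(self, node: int) -> float:
        """Merge height of a node (0 for leaves)."""
        self._check_node(node)
        if node < self.n_leaves:
            return 0.0
        return float(self.Z[node - self.n_leaves, 2])

    def parent(self, node: int) -> int | None:
        self._check_node(node)
        row = self._parent_row.get(node)
        return None if row is None else self.n_leaves + row

    def members(self, node: int) -> list[int]:
        """Leaf indices under a node."""
        self._check_node(node)
        if node < self.n_leaves:
            return [node]
        left, right = int(self.Z[node - self.n_leaves, 0]), \
            int(self.Z[node - self.n_leaves, 1])
        return self.members(left) + self.members(right)

    def _check_node(self, node: int) -> None:
        if not 0 <= node <= 2 * self.n_leaves - 2:
            raise ValueError(f"node {node} not in dendrogram")

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def leaf_order(self) -> list[int]:
        """Display order with larger subtrees second ("sorted by size")."""
        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            left = walk(int(self.Z[node - self.n_leaves, 0]))
            right = walk(int(self.Z[node - self.n_leaves, 1]))
            return left + right if len(left) <= len(right) else right + left
        return walk(self.root)

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences to the parent."""
        def walk(node: int, parent_height: float) -> str:
            h = self.height(node)
            bl = parent_height - h
            if node < self.n_leaves:
                label = self.leaf_labels[node].replace(" ", "_")
                return f"{label}:{bl:.10g}"
            left = int(self.Z[node - self.n_leaves, 0])
            right = int(self.Z[node - self.n_leaves, 1])
            return f"({walk(left, h)},{walk(right, h)}):{bl:.10g}"
        root_h = self.height(self.root)
        inner = walk(self.root, root_h)
        # strip the root's zero-length branch
        return inner.rsplit(":", 1)[0] + ";"

    def merges_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.Z, columns=["left", "right", "height", "count"])


def single_linkage(points: np.ndarray,
                   leaf_labels: list[str] | None = None) -> Dendrogram:
    """Single-linkage agglomeration on Euclidean distances between score vectors.

    Duplicate points are allowed (merge height 0). scipy's implementation
    breaks distance ties deterministically by index order.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    Z = hierarchy.linkage(points, method="single", metric="euclidean")
    return Dendrogram(Z, leaf_labels)


def cluster_metrics(d: Dendrogram, node: int) -> ClusterMetrics:
    """Compactness (merge height) and distinctness (parent height gap) of a node."""
    h = d.height(node)
    parent = d.parent(node)
    distinct = 0.0 if parent is None else d.height(parent) - h
    return ClusterMetrics(cluster_id=node, compactness=h, distinctness=distinct)


def cut_to_classes(d: Dendrogram, K: int) -> np.ndarray:
    """Cut the dendrogram into K groups by removing the K-1 highest merges.

    Returns an integer group id per leaf (0-based, relabelled in leaf
    order). Ties at the cut height resolve by merge order, as recorded in
    the linkage matrix.
    """
    if not 1 <= K <= d.n_leaves:
        raise ValueError(f"K must be in [1, {d.n_leaves}]")
    if K == 1:
        return np.zeros(d.n_leaves, dtype=int)
    labels = hierarchy.fcluster(d.Z, t=K, criterion="maxclust")
    # relabel to 0-based, first-appearance order
    remap: dict[int, int] = {}
    out = np.empty(d.n_leaves, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(int(lab), len(remap))
    return out
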