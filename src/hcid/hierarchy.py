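"""Agglomerative complete-linkage clustering on a precomputed distance matrix.

The linkage engine only ever sees a :class:`~hcid.metrics.DistanceMatrix`
(or a plain square array); it never recomputes distances from raw data, so
the same tree code serves both the interval-valued and the conventional
Euclidean pipelines.

Conventions
-----------
* Cluster ids: leaves are ``1..n``; the cluster created at merge step ``t``
  is ``n + t`` (so internal ids run ``n+1..2n-1``).
* Inter-cluster distance is the maximum over cross-cluster member pairs
  (complete linkage), which makes merge heights non-decreasing.
* Ties on the minimal inter-cluster distance are broken by the
  lexicographically smallest ``(id_a, id_b)`` pair (ids sorted within the
  pair), making runs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import DistanceMatrix

__all__ = ["Dendrogram", "ClusterAssignment", "complete_linkage", "cut", "to_newick"]


@dataclass(frozen=True)
class Dendrogram:
    """The merge tree of an agglomerative clustering.

    ``merges`` is an (n-1, 4) float array with columns
    ``(member_a, member_b, height, new_cluster_id)`` in merge order.
    """

    merges: np.ndarray
    leaf_ids: tuple

    def __post_init__(self):
        merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if merges.shape != (n - 1, 4):
            raise ValueError(f"expected {(n - 1, 4)} merge table, got {merges.shape}")
        heights = merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights decrease; linkage is not monotone")
        object.__setattr__(self, "merges", merges)
        object.__setattr__(self, "leaf_ids", tuple(str(i) for i in self.leaf_ids))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_merge_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.merges, columns=["member_a", "member_b", "height", "new_cluster_id"]
        )
        df.insert(0, "step", np.arange(1, len(df) + 1))
        for c in ("step", "member_a", "member_b", "new_cluster_id"):
            df[c] = df[c].astype(int)
        return df

    def to_scipy_linkage(self) -> np.ndarray:
        """Convert to the (n-1, 4) 0-based linkage format used by scipy.

        Suitable for ``scipy.cluster.hierarchy.dendrogram`` plotting.
        """
        n = self.n_leaves
        sizes = {i: 1 for i in range(1, n + 1)}
        z = np.zeros((n - 1, 4))
        for t, (a, b, h, new) in enumerate(self.merges):
            size = sizes[int(a)] + sizes[int(b)]
            sizes[int(new)] = size
            z[t] = (int(a) - 1, int(b) - 1, h, size)
        return z


@dataclass(frozen=True)
class ClusterAssignment:
    """A flat partition into k clusters labeled 1..k by decreasing size."""

    labels: np.ndarray
    k: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(f"expected exactly clusters 1..{self.k}, got {present}")
        object.__setattr__(self, "labels", labels)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def to_frame(self, obs_ids=None) -> pd.DataFrame:
        ids = list(obs_ids) if obs_ids is not None else list(range(1, len(self.labels) + 1))
        return pd.DataFrame({"obs_id": ids, "cluster": self.labels})


def _validated_square(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.values.copy()
    return DistanceMatrix(np.asarray(d, dtype=float), metric_tag="generic").values.copy()


def complete_linkage(d) -> Dendrogram:
    """Agglomerate by repeatedly merging the closest pair of clusters.

    The distance between two clusters is the maximum pairwise distance of
    their members, maintained by the Lance-Williams complete-linkage
    update ``d(new, k) = max(d(a, k), d(b, k))``.
    """
    if isinstance(d, DistanceMatrix):
        leaf_ids = d.obs_ids
    else:
        leaf_ids = None
    w = _validated_square(d)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations to cluster")
    if leaf_ids is None:
        leaf_ids = tuple(str(i + 1) for i in range(n))

    ids = np.arange(1, n + 1)          # cluster id at each active slot
    active = np.ones(n, dtype=bool)
    np.fill_diagonal(w, np.inf)
    w[:, ~active] = np.inf
    merges = np.zeros((n - 1, 4))

    for step in range(1, n):
        sub = np.where(active)[0]
        block = w[np.ix_(sub, sub)]
        m = block.min()
        # resolve ties by smallest sorted (id_a, id_b)
        ti, tj = np.nonzero(block == m)
        pairs = np.sort(np.stack([ids[sub[ti]], ids[sub[tj]]], axis=1), axis=1)
        best = np.lexsort((pairs[:, 1], pairs[:, 0]))[0]
        id_a, id_b = pairs[best]
        slot_a = sub[np.nonzero(ids[sub] == id_a)[0][0]]
        slot_b = sub[np.nonzero(ids[sub] == id_b)[0][0]]

        new_id = n + step
        merges[step - 1] = (id_a, id_b, m, new_id)

        # Lance-Williams complete-linkage update into slot_a
        merged = np.maximum(w[slot_a], w[slot_b])
        w[slot_a, :] = merged
        w[:, slot_a] = merged
        w[slot_a, slot_a] = np.inf
        active[slot_b] = False
        w[slot_b, :] = np.inf
        w[:, slot_b] = np.inf
        ids[slot_a] = new_id

    return Dendrogram(merges, leaf_ids)


def cut(t: Dendrogram, k: int) -> ClusterAssignment:
    """Undo the last ``k - 1`` merges to obtain a flat k-cluster partition.

    Clusters are relabeled ``1..k`` by decreasing size, ties by smallest
    member index, so cluster 1 is always the largest.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = np.arange(2 * n)  # union-find over cluster ids 1..2n-1

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b, _h, new in t.merges[: n - k]:
        parent[find(int(a))] = int(new)
        parent[find(int(b))] = int(new)

    roots = np.array([find(i) for i in range(1, n + 1)])
    uniq, labels0 = np.unique(roots, return_inverse=True)
    sizes = np.bincount(labels0)
    first_member = np.full(len(uniq), n + 1)
    for i, lab in enumerate(labels0):
        first_member[lab] = min(first_member[lab], i)
    order = np.lexsort((first_member, -sizes))
    rank = np.empty(len(uniq), dtype=int)
    rank[order] = np.arange(1, len(uniq) + 1)
    return ClusterAssignment(rank[labels0], k)


def to_newick(t: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths.

    Each branch length is the parent merge height minus the child's own
    height (leaves have height 0), so root-to-leaf path lengths equal the
    root merge height (an ultrametric tree).
    """
    n = t.n_leaves
    children = {}
    height = {i: 0.0 for i in range(1, n + 1)}
    for a, b, h, new in t.merges:
        children[int(new)] = (int(a), int(b))
        height[int(new)] = float(h)

    def _quote(label: str) -> str:
        if any(c in label for c in " ,():;'\t\n[]"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def render(node: int, parent_h: float) -> str:
        branch = parent_h - height[node]
        if node <= n:
            return f"{_quote(t.leaf_ids[node - 1])}:{branch:.12g}"
        a, b = children[node]
        inner = f"({render(a, height[node])},{render(b, height[node])})"
        return f"{inner}:{branch:.12g}"

    root = int(t.merges[-1, 3]) if n > 1 else 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"
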