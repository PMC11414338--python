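"""Hierarchical clustering of pathways in embedding space.

Pathways are clustered agglomeratively on pairwise distances between
their embedding vectors (cosine distance by default, matching the
cosine geometry of representative-term selection), and the dendrogram
is cut into k flat clusters.  When k is not given it is chosen by
maximizing the mean silhouette width over a small range of candidate
cuts, computed on the same distance matrix used to build the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from pathmrt.io import EmbeddingMatrix

METRICS = ("cosine", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise pathway distance matrix with zero diagonal."""

    pathway_ids: list[str]
    d: np.ndarray  # (n, n) symmetric, zero diagonal
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.pathway_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must be (n, n)")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.pathway_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class ClusterTree:
    """Agglomerative dendrogram over the pathway set (scipy linkage encoding)."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class ClusterAssignment:
    """Flat pathway -> cluster labeling, cluster IDs 1..k.

    Cluster IDs are assigned in dendrogram leaf order of each cluster's
    first member, so the numbering matches the heatmap's visual order.
    """

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        if present != set(range(1, self.k + 1)):
            raise ValueError(
                f"cluster IDs must be exactly 1..{self.k}, got {sorted(present)}"
            )

    def members(self, cluster_id: int) -> list[str]:
        return [p for p, c in self.labels.items() if c == cluster_id]


def compute_distances(
    embeddings: EmbeddingMatrix, metric: str = "cosine"
) -> DistanceMatrix:
    """Pairwise distances between pathway embeddings.

    Cosine distance is ``1 - cos(u, v)``, clipped to [0, 2] against
    floating-point error; euclidean is the usual L2 distance.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    condensed = pdist(embeddings.vectors, metric=metric)
    if metric == "cosine":
        condensed = np.clip(condensed, 0.0, 2.0)
    d = squareform(condensed)
    return DistanceMatrix(pathway_ids=list(embeddings.pathway_ids), d=d, metric=metric)


def build_tree(dist: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerate the distance matrix into a dendrogram.

    Ward linkage presumes euclidean geometry and is rejected for cosine
    distances.  The result is deterministic for a given matrix (scipy
    breaks merge ties by smallest pair index).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if linkage == "ward" and dist.metric != "euclidean":
        raise ValueError(
            "ward linkage requires euclidean distances; "
            "use --metric euclidean or another linkage"
        )
    if dist.n < 2:
        raise ValueError("clustering needs >= 2 pathways")
    Z = hierarchy.linkage(dist.condensed(), method=linkage)
    return ClusterTree(linkage_matrix=Z, leaf_ids=list(dist.pathway_ids))


def _relabel_by_leaf_order(
    raw: np.ndarray, tree: ClusterTree
) -> ClusterAssignment:
    """Renumber arbitrary flat labels to 1..k by dendrogram leaf order."""
    leaves = hierarchy.leaves_list(tree.linkage_matrix)
    first_leaf: dict[int, int] = {}
    for pos, leaf in enumerate(leaves):
        lab = int(raw[leaf])
        first_leaf.setdefault(lab, pos)
    order = sorted(first_leaf, key=first_leaf.__getitem__)
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = {pid: remap[int(raw[i])] for i, pid in enumerate(tree.leaf_ids)}
    return ClusterAssignment(labels=labels, k=len(order))


def cut_tree(
    tree: ClusterTree,
    dist: DistanceMatrix,
    k: int | None = None,
    auto_max_k: int = 20,
) -> ClusterAssignment:
    """Cut the dendrogram into flat clusters.

    With ``k`` given, a standard k-group cut.  With ``k`` absent, k is
    chosen automatically by maximizing mean silhouette width over
    k in {2, ..., min(auto_max_k, n-1)}; ties go to the smallest k.
    """
    n = tree.n_leaves
    if tree.leaf_ids != dist.pathway_ids:
        raise ValueError("tree and distance matrix must cover the same pathways")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
        return _relabel_by_leaf_order(_flat_cut(tree, k), tree)
    if n < 3:
        raise ValueError(
            "automatic cluster-count selection needs >= 3 pathways; pass k explicitly"
        )
    best_k, best_score = None, -np.inf
    for cand in range(2, min(auto_max_k, n - 1) + 1):
        raw = _flat_cut(tree, cand)
        score = silhouette_score(dist.d, raw, metric="precomputed")
        if score > best_score:  # strict: ties keep the smallest k
            best_k, best_score = cand, score
    assert best_k is not None
    return _relabel_by_leaf_order(_flat_cut(tree, best_k), tree)


def _flat_cut(tree: ClusterTree, k: int) -> np.ndarray:
    return hierarchy.fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
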