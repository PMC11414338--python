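"""Most Representative Term selection.

Each cluster is summarized by the arithmetic mean of its members' raw
embedding vectors (the centroid).  The Most Representative Term (MRT)
is the member whose embedding is most cosine-similar to that centroid;
it serves as the cluster's human-readable label.  Ties are broken by
the lexicographically smallest pathway ID so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pathmrt.clustering import ClusterAssignment
from pathmrt.io import EmbeddingMatrix


@dataclass
class ClusterSummary:
    """Centroid, members, MRT and member similarities for one cluster."""

    cluster_id: int
    members: list[str]
    centroid: np.ndarray
    mrt: str
    member_similarities: dict[str, float]

    def __post_init__(self) -> None:
        if self.mrt not in self.members:
            raise ValueError("MRT must be a cluster member")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def mean_similarity(self) -> float:
        return float(np.mean(list(self.member_similarities.values())))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """``(u . v) / (|u| |v|)``, clipped to [-1, 1] against float error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for the zero vector")
    if np.array_equal(u, v):
        return 1.0  # exact for identical vectors (singleton clusters)
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def cluster_centroid(
    embeddings: EmbeddingMatrix, members: Sequence[str]
) -> np.ndarray:
    """Elementwise arithmetic mean of the members' raw embedding vectors.

    Vectors are averaged as given, without unit-normalization; cosine
    similarity to the centroid is measured afterwards.
    """
    if not members:
        raise ValueError("cluster must have at least one member")
    rows = np.stack([embeddings.row(pid) for pid in members])
    return rows.mean(axis=0)


def select_mrt(
    embeddings: EmbeddingMatrix,
    members: Sequence[str],
    centroid: np.ndarray,
) -> tuple[str, dict[str, float]]:
    """Member most cosine-similar to the centroid, plus all similarities.

    Ties are broken by lexicographically smallest pathway ID.  A zero
    centroid (perfectly antipodal members) is a hard error.
    """
    if not members:
        raise ValueError("cluster must have at least one member")
    if np.linalg.norm(np.asarray(centroid, dtype=float)) == 0.0:
        raise ValueError(
            f"cluster of {list(members)} has a zero centroid "
            "(members are perfectly antipodal); cosine to centroid is undefined"
        )
    sims = {pid: cosine_similarity(embeddings.row(pid), centroid) for pid in members}
    mrt = min(sims, key=lambda pid: (-sims[pid], pid))
    return mrt, sims


def summarize_clusters(
    embeddings: EmbeddingMatrix, assignment: ClusterAssignment
) -> list[ClusterSummary]:
    """One :class:`ClusterSummary` per cluster ID 1..k, in ID order."""
    missing = [p for p in embeddings.pathway_ids if p not in assignment.labels]
    if missing:
        raise ValueError(f"assignment does not cover pathways: {missing}")
    out = []
    for cid in range(1, assignment.k + 1):
        # keep embedding row order within the cluster for reproducibility
        members = [p for p in embeddings.pathway_ids if assignment.labels[p] == cid]
        centroid = cluster_centroid(embeddings, members)
        mrt, sims = select_mrt(embeddings, members, centroid)
        out.append(
            ClusterSummary(
                cluster_id=cid,
                members=members,
                centroid=centroid,
                mrt=mrt,
                member_similarities=sims,
            )
        )
    return out
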