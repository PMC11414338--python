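"""2-D UMAP layout of the pathway embeddings for the scatterplot.

The layout is presentation-only: cluster membership and MRT selection
never depend on it, which keeps the one stochastic stage of the
pipeline out of the scientific core.  With a fixed seed UMAP runs
single-threaded and the coordinates are reproducible within one
environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pathmrt.io import EmbeddingMatrix


@dataclass
class Layout2D:
    pathway_ids: list[str]
    coords: np.ndarray  # (n, 2)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.pathway_ids), 2):
            raise ValueError("coords must be an (n, 2) matrix")
        if not np.isfinite(self.coords).all():
            raise ValueError("layout coordinates must be finite")


def compute_layout(
    embeddings: EmbeddingMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "cosine",
    seed: int = 42,
) -> Layout2D:
    """Embed the pathway vectors into 2-D with UMAP.

    Parameters mirror umap-learn's: ``n_neighbors`` controls the
    local/global balance, ``min_dist`` the packing density.  The cosine
    metric matches the clustering geometry.  Requires n >= 4 pathways
    and ``n_neighbors`` < n.
    """
    n = embeddings.n_pathways
    if n < 4:
        raise ValueError(f"UMAP layout needs >= 4 pathways, got {n}")
    if n_neighbors >= n:
        raise ValueError(
            f"n_neighbors ({n_neighbors}) must be < number of pathways ({n}); "
            "lower --n-neighbors"
        )
    if not 0.0 < min_dist < 1.0:
        raise ValueError(f"min_dist must lie in (0, 1), got {min_dist}")
    import umap  # deferred: numba JIT makes this import expensive

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(embeddings.vectors)
    return Layout2D(
        pathway_ids=list(embeddings.pathway_ids),
        coords=np.asarray(coords, dtype=float),
        params={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "metric": metric,
            "seed": seed,
        },
    )


def write_layout(
    layout: Layout2D, path: str | Path, assignment=None
) -> Path:
    """Write the layout as TSV with a metadata header line.

    Columns: pathway_id, x, y and, when an assignment is given,
    cluster_id.  The first line records the UMAP parameters verbatim.
    """
    path = Path(path)
    p = layout.params
    meta = "# " + " ".join(f"{k}={p[k]}" for k in sorted(p))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(meta + "\n")
        cols = ["pathway_id", "x", "y"] + (["cluster_id"] if assignment else [])
        fh.write("\t".join(cols) + "\n")
        for pid, (x, y) in zip(layout.pathway_ids, layout.coords):
            row = [pid, repr(float(x)), repr(float(y))]
            if assignment:
                row.append(str(assignment.labels[pid]))
            fh.write("\t".join(row) + "\n")
    return path
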