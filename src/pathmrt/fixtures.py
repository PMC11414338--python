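"""Synthetic inputs with known cluster structure.

The generator emulates both pipeline inputs without any download:
cluster directions are random unit vectors kept mutually separated
(all pairwise cosines < 0.5), member embeddings are a direction plus
isotropic Gaussian noise, and enrichment metrics are drawn per
(cluster, analysis) around a cluster-level mean effect.  Everything is
deterministic given the seed, and the ground-truth partition is
returned for recovery benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pathmrt.io import EmbeddingMatrix, EnrichmentTable

_DIRECTION_COS_MAX = 0.5  # separation guard: keeps clusters identifiable
_WITHIN_SD = 0.25  # sd of enrichment values around the cluster-analysis mean


@dataclass
class FixtureConfig:
    """Parameters of the synthetic generator.

    noise_sd is the sd of isotropic Gaussian noise added to each unit
    cluster-direction vector (angular spread); effect_sd is the sd of
    the per-(cluster, analysis) mean enrichment.
    """

    n_clusters: int = 5
    sizes: list[int] = field(default_factory=lambda: [20] * 5)
    dim: int = 16
    noise_sd: float = 0.05
    n_analyses: int = 2
    effect_sd: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.sizes) != self.n_clusters:
            raise ValueError("sizes must list one count per cluster")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every cluster needs >= 1 member")
        if sum(self.sizes) < 2:
            raise ValueError("fixture needs >= 2 pathways in total")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be > 0")


def _separated_directions(
    rng: np.random.Generator, n_clusters: int, dim: int
) -> np.ndarray:
    """Random unit vectors with all pairwise cosines < 0.5 (rejection)."""
    dirs: list[np.ndarray] = []
    attempts = 0
    while len(dirs) < n_clusters:
        v = rng.standard_normal(dim)
        v /= np.linalg.norm(v)
        if all(float(np.dot(v, u)) < _DIRECTION_COS_MAX for u in dirs):
            dirs.append(v)
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError(
                f"could not place {n_clusters} separated directions in "
                f"{dim} dimensions; increase dim or reduce n_clusters"
            )
    return np.stack(dirs)


def generate_fixture(
    config: FixtureConfig,
) -> tuple[EmbeddingMatrix, EnrichmentTable, dict[str, int]]:
    """Generate (embeddings, enrichment table, ground-truth partition).

    Ground truth maps each synthetic pathway ID to its generating
    cluster index (1-based, in generation order).
    """
    rng = np.random.default_rng(config.seed)
    directions = _separated_directions(rng, config.n_clusters, config.dim)

    ids: list[str] = []
    vectors: list[np.ndarray] = []
    truth: dict[str, int] = {}
    counter = 0
    for c, size in enumerate(config.sizes):
        for _ in range(size):
            counter += 1
            pid = f"GO:SYN{counter:05d}"
            ids.append(pid)
            vectors.append(
                directions[c] + rng.normal(0.0, config.noise_sd, config.dim)
            )
            truth[pid] = c + 1

    # per-(cluster, analysis) mean effects, then member values around them
    mu = rng.normal(0.0, config.effect_sd, (config.n_clusters, config.n_analyses))
    values = np.empty((len(ids), config.n_analyses))
    row = 0
    for c, size in enumerate(config.sizes):
        values[row : row + size] = rng.normal(
            mu[c], _WITHIN_SD, (size, config.n_analyses)
        )
        row += size

    embeddings = EmbeddingMatrix(pathway_ids=list(ids), vectors=np.stack(vectors))
    table = EnrichmentTable(
        pathway_ids=list(ids),
        analysis_names=[f"analysis_{j + 1}" for j in range(config.n_analyses)],
        values=values,
    )
    return embeddings, table, truth
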