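"""End-to-end pipeline orchestration.

``run_pipeline`` reads and aligns the two inputs, clusters, selects
MRTs, computes the UMAP layout, renders both figures, and writes all
tabular exports plus a JSON run manifest capturing every parameter,
input checksums and the tool version -- enough to re-execute an
identical run.  On a stage failure the manifest records which stage
failed and which artifacts were already produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from pathmrt import io as pio
from pathmrt.clustering import build_tree, compute_distances, cut_tree
from pathmrt.layout import compute_layout, write_layout
from pathmrt.mrt import summarize_clusters
from pathmrt.viz import FigureSpec, render_heatmap, render_scatterplot

logger = logging.getLogger("pathmrt")


@dataclass
class RunConfig:
    input_path: str
    embeddings_path: str
    output_dir: str
    metric: str = "cosine"
    linkage: str = "average"
    clusters: int | None = None
    auto_max_k: int = 20
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 42
    figure_format: str = "png"
    dpi: int = 150
    log_level: str = "INFO"


class StageError(RuntimeError):
    """Wraps an exception with the name of the pipeline stage it broke."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest as a dict."""
    from pathmrt import __version__

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_file = out_dir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("pathmrt")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "tool": "pathmrt",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": asdict(config),
        "inputs": {},
        "artifacts": [],
        "status": "RUNNING",
    }
    manifest_path = out_dir / "run_manifest.json"
    stage = "read inputs"
    try:
        table = pio.read_enrichment_table(config.input_path)
        embeddings = pio.read_embeddings(config.embeddings_path)
        manifest["inputs"] = {
            "enrichment_table": {
                "path": str(config.input_path),
                "sha256": _sha256(Path(config.input_path)),
                "n_pathways": table.n_pathways,
                "n_analyses": table.n_analyses,
            },
            "embeddings": {
                "path": str(config.embeddings_path),
                "sha256": _sha256(Path(config.embeddings_path)),
                "n_pathways": embeddings.n_pathways,
                "dim": embeddings.dim,
            },
        }

        stage = "align"
        aligned = pio.align_inputs(table, embeddings)
        manifest["aligned_pathways"] = aligned.table.n_pathways
        manifest["dropped_from_table"] = aligned.dropped_from_table
        manifest["dropped_from_embeddings"] = aligned.dropped_from_embeddings

        stage = "cluster"
        dist = compute_distances(aligned.embeddings, metric=config.metric)
        tree = build_tree(dist, linkage=config.linkage)
        assignment = cut_tree(
            tree, dist, k=config.clusters, auto_max_k=config.auto_max_k
        )
        manifest["k"] = assignment.k
        logger.info("clustered %d pathways into k=%d", dist.n, assignment.k)

        stage = "select MRTs"
        summaries = summarize_clusters(aligned.embeddings, assignment)
        for s in summaries:
            logger.info(
                "cluster %d (n=%d): MRT %s (cos=%.4f)",
                s.cluster_id, s.size, s.mrt, s.member_similarities[s.mrt],
            )

        stage = "write cluster tables"
        clusters_tsv = out_dir / "clusters.tsv"
        pio.write_cluster_table(summaries, assignment, clusters_tsv)
        manifest["artifacts"].append(str(clusters_tsv))

        mrt_tsv = out_dir / "mrt_summary.tsv"
        pd.DataFrame(
            [
                (s.cluster_id, s.mrt, s.size, s.mean_similarity)
                for s in summaries
            ],
            columns=["cluster_id", "mrt_id", "size", "mean_similarity"],
        ).to_csv(mrt_tsv, sep="\t", index=False)
        manifest["artifacts"].append(str(mrt_tsv))

        stage = "layout"
        layout = compute_layout(
            aligned.embeddings,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            metric=config.metric,
            seed=config.seed,
        )
        layout_tsv = out_dir / "layout.tsv"
        write_layout(layout, layout_tsv, assignment=assignment)
        manifest["artifacts"].append(str(layout_tsv))

        stage = "render figures"
        fmt = config.figure_format
        heatmap = render_heatmap(
            aligned.table,
            assignment,
            summaries,
            FigureSpec(
                output_path=out_dir / f"heatmap.{fmt}",
                format=fmt,
                dpi=config.dpi,
                palette_seed=config.seed,
            ),
        )
        manifest["artifacts"] += [str(heatmap), str(out_dir / "heatmap_rows.tsv")]
        scatter = render_scatterplot(
            layout,
            assignment,
            summaries,
            aligned.table,
            FigureSpec(
                output_path=out_dir / f"scatterplot.{fmt}",
                format=fmt,
                dpi=config.dpi,
                palette_seed=config.seed,
            ),
        )
        manifest["artifacts"] += [
            str(scatter),
            str(out_dir / "scatterplot_points.tsv"),
        ]

        manifest["status"] = "OK"
        return manifest
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        raise StageError(stage, exc) from exc
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        root.removeHandler(handler)
        handler.close()
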