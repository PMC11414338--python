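"""Publication-style figures: cluster-annotated enrichment heatmap and
cluster-colored UMAP scatterplot.

Every render also writes a machine-readable sidecar TSV (row order for
the heatmap, point table for the scatterplot) so plot semantics can be
asserted in tests without pixel comparison.
"""

from __future__ import annotations

import colorsys
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; figures are written to files only
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from pathmrt.clustering import ClusterAssignment
from pathmrt.io import EnrichmentTable
from pathmrt.layout import Layout2D
from pathmrt.mrt import ClusterSummary

FORMATS = ("png", "svg", "pdf")
_MARKERS = ("o", "s", "^", "D", "v", "P")


@dataclass
class FigureSpec:
    """Output and styling parameters shared by both figures."""

    output_path: str | Path
    format: str = "png"
    width: float = 8.0
    height: float = 6.0
    dpi: int = 150
    palette_seed: int = 0

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.format!r}")


def cluster_palette(k: int, palette_seed: int = 0) -> list[str]:
    """k distinct cluster colors, maximally spaced in hue.

    A pure function of (k, palette_seed): the seed only rotates the hue
    wheel so reruns are deterministic.
    """
    rng = np.random.default_rng(palette_seed)
    offset = float(rng.random())
    colors = []
    for i in range(k):
        h = (offset + i / k) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.65, 0.85)
        colors.append(f"#{int(r * 255):02x}{int(g * 255):02x}{int(b * 255):02x}")
    return colors


def _heatmap_row_order(
    assignment: ClusterAssignment, summaries: list[ClusterSummary]
) -> list[tuple[str, int, float, int]]:
    """(pathway, cluster, cosine, is_mrt) rows: clusters in ID order,
    members by descending cosine-to-centroid, ties by pathway ID."""
    rows = []
    for s in sorted(summaries, key=lambda s: s.cluster_id):
        members = sorted(
            s.members, key=lambda p: (-s.member_similarities[p], p)
        )
        for pid in members:
            rows.append(
                (pid, s.cluster_id, s.member_similarities[pid], int(pid == s.mrt))
            )
    return rows


def render_heatmap(
    table: EnrichmentTable,
    assignment: ClusterAssignment,
    summaries: list[ClusterSummary],
    spec: FigureSpec,
) -> Path:
    """Cluster-annotated enrichment heatmap.

    Rows are pathways grouped contiguously by cluster; columns are
    analyses.  Cell color encodes the enrichment metric on a diverging
    scale symmetric about zero (GSEA-style scores are signed); missing
    cells are blank.  A left-hand strip shows the cluster color and
    each cluster is labeled with its MRT.
    """
    out = Path(spec.output_path)
    rows = _heatmap_row_order(assignment, summaries)
    palette = cluster_palette(assignment.k, spec.palette_seed)
    frame = table.to_frame()
    data = frame.loc[[r[0] for r in rows]].to_numpy()

    finite = np.isfinite(data)
    vmax = float(np.abs(data[finite]).max()) if finite.any() else 1.0
    vmax = vmax or 1.0

    fig, (ax_strip, ax) = plt.subplots(
        1,
        2,
        figsize=(spec.width, spec.height),
        gridspec_kw={"width_ratios": [0.04, 0.96], "wspace": 0.02},
    )
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("white")
    mesh = ax.pcolormesh(masked[::-1], cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(np.arange(len(table.analysis_names)) + 0.5)
    ax.set_xticklabels(table.analysis_names, rotation=45, ha="right", fontsize=8)
    ax.set_yticks([])

    # cluster color strip + MRT labels (rows plotted top-to-bottom)
    n = len(rows)
    strip = np.array(
        [matplotlib.colors.to_rgb(palette[r[1] - 1]) for r in rows]
    ).reshape(n, 1, 3)
    ax_strip.imshow(strip, aspect="auto", extent=(0, 1, 0, n), origin="upper")
    ax_strip.set_xticks([])
    ax_strip.set_yticks([])
    mrt_by_cluster = {s.cluster_id: s.mrt for s in summaries}
    top = 0
    for cid in range(1, assignment.k + 1):
        size = sum(1 for r in rows if r[1] == cid)
        ax_strip.text(
            -0.3,
            n - (top + size / 2),
            mrt_by_cluster[cid],
            ha="right",
            va="center",
            fontsize=7,
        )
        top += size
    fig.colorbar(mesh, ax=ax, label="Enrichment score", shrink=0.6)
    fig.savefig(out, format=spec.format, dpi=spec.dpi, bbox_inches="tight")
    plt.close(fig)

    sidecar = out.with_name(out.stem + "_rows.tsv")
    pd.DataFrame(
        [
            (i, pid, cid, palette[cid - 1], is_mrt, cos)
            for i, (pid, cid, cos, is_mrt) in enumerate(rows)
        ],
        columns=[
            "row_index",
            "pathway_id",
            "cluster_id",
            "cluster_color",
            "is_mrt",
            "cosine_to_centroid",
        ],
    ).to_csv(sidecar, sep="\t", index=False)
    return out


def render_scatterplot(
    layout: Layout2D,
    assignment: ClusterAssignment,
    summaries: list[ClusterSummary],
    table: EnrichmentTable,
    spec: FigureSpec,
    label_mrts: bool = True,
) -> Path:
    """Cluster-colored 2-D UMAP scatterplot.

    One point per (pathway, analysis) pair with a non-missing metric;
    color encodes cluster, marker shape encodes analysis.  With more
    than 6 analyses shape coding saturates, so the plot falls back to
    color-only per-analysis panels (with a warning).
    """
    out = Path(spec.output_path)
    palette = cluster_palette(assignment.k, spec.palette_seed)
    frame = table.to_frame()
    coords = {pid: xy for pid, xy in zip(layout.pathway_ids, layout.coords)}
    mrts = {s.mrt for s in summaries}

    points = []  # (pathway, analysis, x, y, cluster, color, marker)
    panels = len(table.analysis_names) > len(_MARKERS)
    if panels:
        warnings.warn(
            f"{len(table.analysis_names)} analyses exceed the {len(_MARKERS)} "
            "available marker shapes; falling back to color-only panels",
            stacklevel=2,
        )
    for j, analysis in enumerate(table.analysis_names):
        marker = "o" if panels else _MARKERS[j]
        for pid in layout.pathway_ids:
            if not np.isfinite(frame.at[pid, analysis]):
                continue
            x, y = coords[pid]
            cid = assignment.labels[pid]
            points.append(
                (pid, analysis, float(x), float(y), cid, palette[cid - 1], marker)
            )

    if panels:
        ncol = min(3, len(table.analysis_names))
        nrow = int(np.ceil(len(table.analysis_names) / ncol))
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(spec.width, spec.height), squeeze=False
        )
        axmap = {a: axes.flat[j] for j, a in enumerate(table.analysis_names)}
        for ax in axes.flat[len(table.analysis_names):]:
            ax.set_visible(False)
    else:
        fig, ax = plt.subplots(figsize=(spec.width, spec.height))
        axmap = {a: ax for a in table.analysis_names}

    for analysis in table.analysis_names:
        pts = [p for p in points if p[1] == analysis]
        if not pts:
            continue
        axmap[analysis].scatter(
            [p[2] for p in pts],
            [p[3] for p in pts],
            c=[p[5] for p in pts],
            marker=pts[0][6],
            s=22,
            edgecolors="none",
            alpha=0.85,
        )
    for analysis, ax in axmap.items():
        if panels:
            ax.set_title(analysis, fontsize=9)
        ax.set_xlabel("UMAP 1", fontsize=8)
        ax.set_ylabel("UMAP 2", fontsize=8)
    if label_mrts:
        for pid in mrts:
            x, y = coords[pid]
            next(iter(axmap.values())).annotate(
                pid, (x, y), fontsize=6, textcoords="offset points", xytext=(2, 2)
            )
    if not panels and len(table.analysis_names) > 1:
        handles = [
            plt.Line2D(
                [], [], linestyle="", marker=_MARKERS[j], color="gray", label=a
            )
            for j, a in enumerate(table.analysis_names)
        ]
        next(iter(axmap.values())).legend(
            handles=handles, fontsize=7, title="Analysis", title_fontsize=8
        )
    fig.savefig(out, format=spec.format, dpi=spec.dpi, bbox_inches="tight")
    plt.close(fig)

    sidecar = out.with_name(out.stem + "_points.tsv")
    pd.DataFrame(
        points,
        columns=["pathway_id", "analysis", "x", "y", "cluster_id", "color", "marker"],
    ).to_csv(sidecar, sep="\t", index=False)
    return out
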