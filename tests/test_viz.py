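import numpy as np
import pandas as pd
import pytest

from pathmrt.clustering import ClusterAssignment
from pathmrt.io import EnrichmentTable
from pathmrt.layout import Layout2D
from pathmrt.mrt import summarize_clusters
from pathmrt.viz import (
    FigureSpec,
    cluster_palette,
    render_heatmap,
    render_scatterplot,
)


@pytest.fixture
def small_clustering(tiny_embeddings):
    assignment = ClusterAssignment(
        labels={"GO:A": 1, "GO:B": 1, "GO:C": 2, "GO:D": 2}, k=2
    )
    summaries = summarize_clusters(tiny_embeddings, assignment)
    return assignment, summaries


@pytest.fixture
def small_layout(tiny_embeddings):
    rng = np.random.default_rng(0)
    return Layout2D(
        pathway_ids=list(tiny_embeddings.pathway_ids),
        coords=rng.standard_normal((4, 2)),
        params={"n_neighbors": 3, "min_dist": 0.1, "metric": "cosine", "seed": 0},
    )


def test_palette_distinct_and_deterministic():
    for k in (1, 2, 5, 12):
        pal = cluster_palette(k, palette_seed=3)
        assert len(pal) == k == len(set(pal))
    assert cluster_palette(5, 3) == cluster_palette(5, 3)
    assert cluster_palette(5, 3) != cluster_palette(5, 4)


def test_heatmap_sidecar_row_order(tmp_path, tiny_table, small_clustering):
    assignment, summaries = small_clustering
    spec = FigureSpec(output_path=tmp_path / "h.png", palette_seed=1)
    out = render_heatmap(tiny_table, assignment, summaries, spec)
    assert out.exists() and out.stat().st_size > 0
    side = pd.read_csv(tmp_path / "h_rows.tsv", sep="\t")
    assert list(side.columns) == [
        "row_index",
        "pathway_id",
        "cluster_id",
        "cluster_color",
        "is_mrt",
        "cosine_to_centroid",
    ]
    # clusters contiguous and ascending; cosine descending inside each
    assert list(side.cluster_id) == sorted(side.cluster_id)
    for cid, grp in side.groupby("cluster_id"):
        sims = list(grp.cosine_to_centroid)
        assert sims == sorted(sims, reverse=True)
        assert grp.is_mrt.sum() == 1
    # one color per cluster, consistent with the palette
    pal = cluster_palette(2, palette_seed=1)
    for cid, grp in side.groupby("cluster_id"):
        assert set(grp.cluster_color) == {pal[cid - 1]}


def test_heatmap_all_missing_column(tmp_path, small_clustering, tiny_embeddings):
    assignment, summaries = small_clustering
    table = EnrichmentTable(
        pathway_ids=list(tiny_embeddings.pathway_ids),
        analysis_names=["real", "empty"],
        values=np.column_stack([np.arange(4.0), np.full(4, np.nan)]),
    )
    spec = FigureSpec(output_path=tmp_path / "h.png")
    out = render_heatmap(table, assignment, summaries, spec)
    assert out.exists() and out.stat().st_size > 0


def test_heatmap_rerun_sidecar_identical(tmp_path, tiny_table, small_clustering):
    assignment, summaries = small_clustering
    for name in ("a", "b"):
        render_heatmap(
            tiny_table,
            assignment,
            summaries,
            FigureSpec(output_path=tmp_path / f"{name}.png", palette_seed=7),
        )
    assert (tmp_path / "a_rows.tsv").read_bytes() == (
        tmp_path / "b_rows.tsv"
    ).read_bytes()


def test_scatterplot_point_semantics(
    tmp_path, tiny_table, small_clustering, small_layout
):
    assignment, summaries = small_clustering
    spec = FigureSpec(output_path=tmp_path / "s.png", palette_seed=1)
    out = render_scatterplot(small_layout, assignment, summaries, tiny_table, spec)
    assert out.exists() and out.stat().st_size > 0
    pts = pd.read_csv(tmp_path / "s_points.tsv", sep="\t")
    # one point per (pathway, analysis) with a non-missing metric:
    # tiny_table has one NaN (GO:B, down), so 4*2 - 1 = 7 points
    assert len(pts) == 7
    assert not ((pts.pathway_id == "GO:B") & (pts.analysis == "down")).any()
    # pathway tested in 2 analyses: identical coords, different markers
    both = pts[pts.pathway_id == "GO:A"]
    assert len(both) == 2
    assert both.x.nunique() == 1 and both.y.nunique() == 1
    assert both.marker.nunique() == 2
    # color encodes cluster
    pal = cluster_palette(2, palette_seed=1)
    for _, row in pts.iterrows():
        assert row.color == pal[assignment.labels[row.pathway_id] - 1]


def test_scatterplot_five_cluster_palette(tmp_path, default_fixture):
    emb, table, truth = default_fixture
    assignment = ClusterAssignment(labels=dict(truth), k=5)
    summaries = summarize_clusters(emb, assignment)
    rng = np.random.default_rng(1)
    layout = Layout2D(
        pathway_ids=list(emb.pathway_ids),
        coords=rng.standard_normal((emb.n_pathways, 2)),
        params={},
    )
    spec = FigureSpec(output_path=tmp_path / "s.png", palette_seed=0)
    render_scatterplot(layout, assignment, summaries, table, spec)
    pts = pd.read_csv(tmp_path / "s_points.tsv", sep="\t")
    assert pts.color.nunique() == 5


def test_scatterplot_many_analyses_fall_back_to_panels(
    tmp_path, small_clustering, small_layout, tiny_embeddings
):
    assignment, summaries = small_clustering
    table = EnrichmentTable(
        pathway_ids=list(tiny_embeddings.pathway_ids),
        analysis_names=[f"a{j}" for j in range(7)],
        values=np.ones((4, 7)),
    )
    spec = FigureSpec(output_path=tmp_path / "s.png")
    with pytest.warns(UserWarning, match="marker shapes"):
        render_scatterplot(small_layout, assignment, summaries, table, spec)
    pts = pd.read_csv(tmp_path / "s_points.tsv", sep="\t")
    assert set(pts.marker) == {"o"}  # color-only panels
    assert len(pts) == 28


def test_scatterplot_single_analysis_single_marker(
    tmp_path, small_clustering, small_layout, tiny_embeddings
):
    assignment, summaries = small_clustering
    table = EnrichmentTable(
        pathway_ids=list(tiny_embeddings.pathway_ids),
        analysis_names=["only"],
        values=np.ones((4, 1)),
    )
    spec = FigureSpec(output_path=tmp_path / "s.svg", format="svg")
    render_scatterplot(small_layout, assignment, summaries, table, spec)
    pts = pd.read_csv(tmp_path / "s_points.tsv", sep="\t")
    assert pts.marker.nunique() == 1 and len(pts) == 4


def test_figure_spec_rejects_unknown_format(tmp_path):
    with pytest.raises(ValueError, match="format"):
        FigureSpec(output_path=tmp_path / "x.bmp", format="bmp")
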