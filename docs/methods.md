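# Methods

## Model and procedure

`pathmrt` treats a pathway (a GO term, KEGG pathway, WikiPathways entry,
…) as a point in an embedding space in which angular proximity
approximates semantic relatedness. Given n pathways with embedding
vectors x₁…xₙ ∈ ℝᵈ, the pipeline is:

1. Pairwise distances dᵢⱼ = 1 − cos(xᵢ, xⱼ) (cosine distance, clipped to
   [0, 2] against floating-point error). Euclidean distance is available
   as an alternative.
2. Agglomerative hierarchical clustering of the distance matrix
   (average linkage by default; complete and ward are supported, ward
   only with euclidean distances since its variance objective presumes
   euclidean geometry).
3. A flat cut of the dendrogram into k clusters. If k is not supplied it
   is chosen by maximizing the mean silhouette width, computed on the
   same distance matrix, over k ∈ {2, …, min(auto_max_k, n−1)}; ties go
   to the smallest k. Cluster IDs 1..k are assigned in dendrogram leaf
   order of each cluster's first member, so numbering matches the
   heatmap's top-to-bottom visual order.
4. Per cluster, the centroid c = mean of the members' **raw** embedding
   vectors, and the Most Representative Term (MRT) = the member with the
   largest cos(xᵢ, c). Ties are broken by lexicographically smallest
   pathway ID.
5. Presentation: a 2-D UMAP of the embeddings (cosine metric, fixed
   seed) and the two figures. The layout is strictly presentation-only —
   no scientific output depends on it.

Assumptions worth stating: the embeddings are taken as given and
meaningful (garbage embeddings produce confidently-labeled garbage
clusters); enrichment metrics play no role in clustering or MRT
selection, they are only rendered; and the cosine geometry is the right
notion of term similarity, which is the premise of embedding-based
summarization generally.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `metric` | cosine | distance for clustering; matches the cosine-based MRT criterion so both stages share one geometry |
| `linkage` | average | robust default for non-euclidean dissimilarities |
| `clusters` (k) | auto | silhouette maximization is fully reproducible and requires no tuning; users can pin k |
| `auto_max_k` | 20 | more than ~20 clusters defeats the purpose of summarization |
| `n_neighbors` | 15 | conventional UMAP default; must be < n |
| `min_dist` | 0.1 | conventional UMAP default, in (0, 1) |
| `seed` | 42 | seeds UMAP and the figure palette; clustering and MRT selection are deterministic and need no seed |

### Centroid of raw vs unit-normalized vectors

Averaging the raw member vectors is the literal reading of "average
embedding". The alternative — averaging unit-normalized vectors — changes
the centroid direction whenever member norms differ, and the two
coincide exactly for embedding models that emit constant-norm vectors.
We average raw vectors and document the choice here; it is exposed
nowhere as an option to keep the method's definition unambiguous.

### Tie-breaking

Cosine ties for the MRT (exactly symmetric members) are resolved by the
lexicographically smallest pathway ID. Any deterministic rule would do;
this one is stable across platforms and requires no extra state.

## Synthetic data generator

The generator emulates the two inputs with known ground truth. Cluster
directions are random unit vectors in ℝᵈ, rejection-sampled until all
pairwise cosines are < 0.5 so the planted structure is identifiable.
Member embeddings are direction + isotropic Gaussian noise (sd
`noise_sd`, default 0.05 — roughly a 3° angular spread at d = 16, i.e.
tight, well-separated clusters). Enrichment values for cluster c in
analysis j are Normal(μ_cj, 0.25²) with μ_cj ~ Normal(0, effect_sd²),
giving signed GSEA-like scores that are coherent within a cluster;
defaults are 2 analyses and effect_sd = 1, a realistic two-contrast
comparison where between-cluster effect spread dominates within-cluster
scatter. Everything derives from one `numpy` Generator seed.

What the generator does **not** emulate: real embedding-model geometry
(anisotropy, hubness, non-uniform norms), overlapping or hierarchically
nested pathway families, heavy-tailed cluster sizes, and missingness
patterns of real multi-contrast tables. Passing the recovery benchmarks
therefore shows the pipeline is correct and stable on separable
directional data, not that any particular real dataset will yield five
clean clusters.

## Numerical choices

- Cosine similarities are clipped to [−1, 1] and cosine distances to
  [0, 2]; identical vectors return exactly 1.0 (relevant for singleton
  clusters, whose centroid equals the member).
- A zero embedding row is rejected at load (cosine undefined); a zero
  cluster centroid (perfectly antipodal members) is a hard error naming
  the cluster rather than a silent NaN.
- Tabular floats are written with `%.17g`, and parsed with Python's
  correctly-rounded `float()`, so write→read round-trips are exact at
  full double precision.
- Missing enrichment cells are carried as NaN, rendered blank in the
  heatmap, and never reach the clustering stage.
- Merge ties in the linkage are resolved by scipy's deterministic
  smallest-index rule; silhouette ties by smallest k.

## Benchmark sizes

The standing benchmark is 5 clusters × 20 pathways at d = 16 — large
enough that silhouette selection, recovery (ARI) and UMAP separation are
non-trivial, small enough that the whole suite and the acceptance script
each run in well under a minute of compute after JIT warm-up. The MRT
oracle check uses 200 random instances with n ≤ 8 and d ≤ 6, where
exhaustive search is exact and instant.

## Known limitations

- UMAP coordinates are reproducible for a fixed seed within one
  software environment, not across umap-learn/numba versions; hence all
  scientific outputs are computed upstream of the layout.
- Automatic k by silhouette favors compact, balanced clusters; strongly
  nested pathway families may be better served by pinning k.
- With more than 6 analyses the scatterplot falls back to per-analysis
  panels, since marker-shape coding saturates.
- Pathway IDs are opaque strings; no ontology structure is used or
  checked beyond collapsing the typesetting space in `GO: 0005739`.
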