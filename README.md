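# cellgraph

Graph-based clustering and characterisation of single-cell RNA-seq data:
from raw UMI count matrices to quality control, multiscale K-nearest-
neighbour manifolds, graph-t-SNE embeddings, "polished Louvain" cell-type
clusters, cluster-level statistics, marker gene sets, neurotransmitter
calls, cell-type taxonomies, and spatial mapping against 3-D voxel
expression atlases. Every stage is exercisable end-to-end on synthetic
data with planted ground truth — no downloads required.

It is written for computational biologists building or auditing cell-type
atlases at desk scale (hundreds to a few thousand cells per run), and as a
tested, self-contained reference implementation of this family of methods.

## The methods at the core

- **Multiscale balanced KNN manifold.** Each cell proposes its k = 100
  nearest neighbours in the space of significant principal components
  (Kolmogorov–Smirnov test against a permutation null), with edge weight
  w(i,j) = 1/rank(j)^alpha; incoming edges are capped at 200 and only
  reciprocated edges enter the mutual graph. Multiscale weights encode
  local and global neighbourhood structure at once.
- **Graph-t-SNE.** t-SNE gradient descent whose affinity matrix is the
  symmetrized, normalized multiscale weight matrix rather than
  perplexity-calibrated Gaussian kernels: the embedding renders the graph
  itself.
- **Polished Louvain.** Weighted Louvain community detection on the mutual
  KNN graph, then outlier rejection (tiny clusters, DBSCAN noise in 2-D,
  disagreement with graph neighbours), density-based splitting of
  suspicious clusters in the standardized embedding, and 10-NN majority
  smoothing — recovering small populations that modularity optimisation
  alone misses.
- **Enrichment score.** E = ((f + 0.1)/(f_out + 0.1)) ·
  ((mu + 0.01)/(mu_out + 0.01)) per gene and cluster, with label-shuffle
  q-values.
- **Trinarization.** Beta-binomial posterior call of each gene as
  expressed / not expressed / indeterminate per cluster:
  theta | n, k ~ Beta(a + k, b + n − k) and P(theta > f) the regularized
  incomplete beta tail, with a = 1.5, b = 2, f = 0.2, PEP = 0.05.
- **Marker gene sets.** Greedy search for up to six genes jointly
  expressed in one cluster but not all expressed in any other, with
  cumulative selectivity (1/matching clusters), specificity (posterior gap
  to the runner-up cluster) and robustness (joint posterior in the target).
- **Taxonomy.** Ward linkage on correlation distances over masked,
  bounded, enrichment-selected cluster profiles, with a branch-stability
  test across the gene-selection parameter.
- **Spatial mapping.** Pearson correlation between z-normalized cluster
  profiles and per-gene voxel "energy" grids, with regional fold
  enrichment of each cluster's top-100 voxels.

See `docs/methods.md` for assumptions, parameter defaults and design
decisions.

## Worked example

```python
import cellgraph as cg

# simulate 2,000 cells in 8 clusters with planted private markers
design = cg.SimulationDesign(seed=1)
m, truth = cg.generate_counts(design)

cg.filter_valid(m)                       # QC masks
valid, graph, clusters = cg.cluster_cells(m, seed=1)

profile = cg.aggregate(m.subset_cells(valid), clusters.labels)
cg.enrichment(profile)
cg.trinarize_profile(profile)
marker = cg.discover_markers(profile, cluster=0)

print("clusters found:", clusters.n_clusters)
print("marker set for cluster 0:", marker.genes)
print("selectivity per prefix:", marker.selectivity)
```

Output:

```
clusters found: 8
marker set for cluster 0: ['Gene00008']
selectivity per prefix: [1.0]
```

All 8 planted clusters are recovered (adjusted Rand index 1.0 against the
planted labels for genuine cells), and a single private marker gene
already identifies cluster 0 uniquely (selectivity 1.0 = the expression
pattern matches exactly one cluster).

The same flow runs from the shell via the `cellgraph` CLI
(`simulate`, `qc`, `classify`, `manifold`, `cluster`, `aggregate`,
`stats`, `markers`, `transmitters`, `taxonomy`, `spatial`, `run-all`);
`run-all` executes the whole pipeline from a YAML config and writes
Loom-dialect files, marker tables, a Newick taxonomy and a run manifest.

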