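# Methods

`cellgraph` implements a graph-based pipeline for clustering single-cell
RNA-seq UMI count data and characterising the resulting cell types:
quality control, two-round manifold learning on a multiscale K-nearest-
neighbour (KNN) graph, graph-t-SNE embedding, "polished Louvain"
clustering, cluster-level statistics (enrichment scores with permutation
q-values and beta-binomial expression calls), greedy marker-gene-set
discovery, neurotransmitter calling, taxonomy construction over cluster
profiles, and correlation mapping against a 3-D voxel expression atlas.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Quality control and classification

Cells are valid when they carry >= 600 UMIs and >= 1.2 UMIs per detected
gene; genes are valid when detected in >= 20 cells and <= 60% of cells.
Filters apply per input sample when sample ids are present; a gene is kept
when it passes in at least one sample (a gene ubiquitous in one tissue can
be informative in another). The filters are idempotent — masks are always
recomputed from counts.

The major-class classifier is a linear support-vector machine with Platt
probability calibration over log2(1 + counts-per-5000) features, trained
on up to 100 cells per annotated cluster with an 80/20 split; cycling
variants of a class ("astrocyte, cycling") are pooled with their base
class for reporting, because cycling cells share most of their expression
with non-cycling counterparts. Doublet removal between analysis levels
drops whole clusters whose majority predicted class is a composite
(hyphenated) or configured poor-quality label, then drops individual
cells whose predicted class conflicts with their cluster's majority.

## Manifold learning

1. **Informative genes.** Genes are ranked by the positive offset of their
   log2 coefficient of variation from a support-vector regression (RBF
   kernel, scikit-learn defaults) of log2 CV on log2 mean; the top 1000
   are kept and the sex-linked genes *Xist*/*Tsix* always excluded. In the
   second round, gene selection is cluster-driven instead: the union of
   the 10 most enriched genes per preliminary cluster.
2. **Normalization.** Each cell is scaled to 5,000 molecules over the
   valid genes, log2(x+1)-transformed, and mean-centred per gene. Log base
   2 with pseudocount 1 is used uniformly throughout the package.
3. **Significant components.** PCA is fitted (second round: cells of any
   one cluster capped at 20% of the fitting set, all cells projected) and
   components retained while a two-sample Kolmogorov–Smirnov test against
   a permutation null (each gene's values shuffled independently across
   cells, PCA refitted once) gives p < 0.05, stopping at the first
   failure. The null construction is an implementation decision: it is
   self-contained and matches the intent of dropping components
   indistinguishable from noise. If no component passes, one is retained
   and flagged.
4. **Multiscale balanced KNN.** Each cell proposes its k = 100 Euclidean
   nearest neighbours with weight w = 1/rank^alpha (alpha = 1); each cell
   accepts at most 200 incoming proposals (lowest rank kept, ties to the
   smallest proposing index — deterministic). The mutual graph keeps only
   reciprocated edges, weighted by the mean of the two directed weights.
   Weights are computed only up to rank 100, beyond which they are
   negligible; this also keeps the construction linear in cells.
5. **Graph-t-SNE.** Ordinary t-SNE gradient descent (Student-t kernel,
   early exaggeration 12 for the first 100 of 350 iterations, momentum
   0.5 then 0.8, adaptive gains, learning rate n/48) run with the affinity
   matrix P = (W + W^T)/(2 sum W) from the multiscale weights in place of
   perplexity-calibrated Gaussians. Exact (O(n^2)) gradients are used;
   at the few-thousand-cell scale this package targets, an embedding takes
   tens of seconds. Deterministic given the seed. Disconnected graphs are
   embedded with a warning; components place themselves independently.

## Polished Louvain

Louvain multilevel community detection (igraph, weighted, resolution 1.0)
runs on the mutual KNN graph. Cells are then marked outliers (label −1)
when (1) their cluster has fewer than 10 cells, (2) DBSCAN on the 2-D
embedding (eps = 80th percentile of the distance to the k-th nearest
neighbour, k = min(5 × smoothing_k, 50); min_samples = 10) calls them
noise, or (3) more than 80% of their 10 nearest graph neighbours carry a
different label. Each cluster is standardized in 2-D (PCA-aligned,
mean-subtracted, SD-divided) and re-partitioned by DBSCAN (eps = 70th
percentile, min_samples = max(5% of cells, 25)) when it shows >= 3
median-absolute-deviation outliers at threshold 3.5 or a heavy tail of
isolated cells. Labels are finally smoothed by 10-nearest-neighbour
majority vote (ties to the smaller cluster id; the outlier label
participates but loses ties to real clusters), after which clusters that
fell below 10 cells are re-marked outliers once — smoothing runs before
the final size re-check, an ordering fixed here. Polishing only relabels
to outlier or splits; it never merges Louvain communities. Community ids
are renumbered by decreasing size.

**Known limitation.** Modularity optimisation always partitions: an
unpartitioned graph has modularity 0, so a community holding roughly half
or more of the graph's edges is always re-partitioned, even when it is a
single homogeneous population. The procedure is therefore reliable in the
regime it is designed for — many cell populations, each a modest fraction
of the graph — and recovery there is essentially exact (adjusted Rand
index 1.0 on planted 4- and 8-cluster designs). Datasets containing one
or two populations will be over-split; tests exercise the multi-cluster
regime.

Cluster robustness is assessed with a random forest (100 trees) trained
on a stratified 80% split of log-normalized expression; the report gives
the mean assigned probability of every cluster for held-out cells of each
true cluster, plus per-cluster precision and recall.

## Cluster statistics

**Enrichment.** For gene j in cluster i,
E = ((f + 0.1) / (f_out + 0.1)) * ((mu + 0.01) / (mu_out + 0.01)),
with f the in-cluster detection fraction (detection means UMI count > 0
throughout the package), mu the in-cluster mean count, and the `_out`
quantities computed over all other clustered cells. The constants keep E
finite when the complement statistics vanish. q-values permute cluster
labels across clustered cells (which preserves per-gene marginals — the
interpretation adopted for "shuffling the matrix"), re-aggregate, and use
the add-one estimator q = (1 + #{E_perm >= E_obs}) / (1 + n_shuffles)
with 100 shuffles by default, so q in (0, 1] and is valid under the null.

**Trinarization.** With a gene detected in k of a cluster's n cells and a
Beta(a, b) prior on the population detection frequency theta, the
posterior is Beta(a + k, b + n − k) and
P(theta > f) = 1 − I_f(a + k, b + n − k), the regularized incomplete beta
tail, evaluated with `scipy.special.betaincc` (a stable log-space
implementation; the naive beta/gamma composition overflows at large n).
Defaults a = 1.5, b = 2 (a weak prior slightly favouring "not expressed"),
f = 0.2, PEP = 0.05: *expressed* when P > 0.95, *not expressed* when
P < 0.05, else *indeterminate*. The continuous posterior P is stored in
the "trinaries" layer; calls are derived at read time.

## Marker gene sets and neurotransmitters

The marker set of a cluster starts with its most enriched gene among
genes called expressed there (the expression precondition is enforced,
which the original description leaves open), adds the most specific gene —
the one maximizing the gap between the target's posterior P and the best
other cluster's — and then greedily adds the gene minimizing the number of
clusters in which *all* chosen genes are called expressed, ties broken by
enrichment, stopping at six genes or at selectivity 1. Cumulative
statistics per prefix: selectivity = 1/(matching clusters); specificity =
difference between the best and second-best cluster's joint posterior
(product over genes); robustness = joint posterior in the target cluster,
assuming independence across genes (documented simplification).
Selectivity is monotone non-decreasing (the matching set only shrinks)
and robustness non-increasing.

Neurotransmitter phenotypes are assigned per cluster when *every* gene of
a rule's set passes trinarization at f = 0.05 (f = 0.2 for *Nos1*) and
PEP 0.05; the vesicular glutamate transporters are evaluated as separate
single-gene rules. The rule table ships as an editable default
(YAML-overridable); cluster-specific manual corrections belong in
configuration, never in code.

## Taxonomy

All linkage and distance computations use log2(x+1) profiles. Pan-enriched
genes of each non-neuronal class are those where the fraction of the
class's clusters with an f = 0.05 posterior of ~1 (P > 0.999; the
continuous posterior is used, since thresholds like "> 0.9" imply a
score, not a ternary call) exceeds the fraction of neuronal clusters with
P > 0.9. Pan-enriched, ambient-RNA (*Trf, Plp1, Mog, Mobp, Mfge8, Mbp,
Hbb-bs, H2-DMb2*) and immediate-early (*Fos, Jun, Junb, Egr1*) genes are
zeroed within neuronal clusters; sex genes (*Xist, Tsix, Eif2s3y, Ddx3y,
Uty, Kdm5d*) and *Egr1*/*Jun* are removed everywhere. Each cluster is
bounded to its top 5,000 detected genes and rescaled to a total of
10,000. The top N = 28 enriched genes per cluster are pooled; a first
Ward/Euclidean tree cut at distance 50 defines coarse groups, each
contributing 1.5 N further genes by within-group enrichment (group mean
over column total); the final tree uses correlation distance with Ward
linkage. Ward on a non-Euclidean distance is accepted as specified;
possible height inversions are permitted, not repaired. With masking
disabled the same construction runs on the raw profiles (control mode).

Stability: the tree is rebuilt for every N in 10..44; each branch of the
N = 28 reference is matched to the test branch with maximal Jaccard leaf
overlap (correspondence is otherwise undefined) and scored by (1) Jaccard
>= 0.9 and (2) identical leaf set in identical canonical order (children
ordered by subtree size then smallest leaf id, making "same order"
well-defined). Reported per branch as the fraction of N values satisfying
each criterion.

## Spatial mapping

Atlas genes are high-quality when mean energy > 0.2 over the valid domain
and more than 30 voxels exceed energy 5. Energies are log2(x+1)
transformed and z-normalized per gene with moments taken over
positive-energy voxels; cluster profiles are log2(x+1) z-normalized per
gene across clusters. Pearson correlation over the intersected gene set
gives a cluster × voxel field (NaN outside the valid domain; fewer than
10 usable genes is an error that reports the counts at each filter).
Correlation is computed at the atlas's native (coarse) resolution;
trilinear upsampling is display-only. Regional fold enrichment takes each
cluster's 100 strongest valid voxels (stable tie-break by voxel index)
and divides each region's frequency among them by its frequency among all
valid voxels. The per-gene z-normalization makes the field exactly
invariant to per-gene affine rescaling of the log-energies on strictly
positive atlases; offsets that change the set of zero-energy voxels move
the normalization moments and break exactness (inherent to defining the
moments over positive voxels).

## Synthetic data

The generator emulates droplet scRNA-seq: negative-binomial counts
(variance m + phi m^2, phi = 0.15) with per-gene baseline means drawn
log-normal (sigma = 1.8, so most genes are sparse) and rescaled so the
expected per-cell depth is 2,000 UMIs — depth is a property of the assay,
not of the panel size. Defaults describe the standard test condition:
2,000 cells, 2,000 genes, 8 equal clusters, 10 private markers per
cluster. Markers are anchored at the NB mean whose baseline detection is
0.1 and elevated 30-fold in the home cluster, making them private in the
trinarization sense (out-of-cluster detection below f = 0.2, in-cluster
~0.93) while keeping them under the 60%-detection QC ceiling. Doublets
(2%) are NB draws from the sum of two random cells' expected profiles and
carry the label "doublet", never a cluster id; low-quality cells (2%) are
binomially downsampled below 600 total UMIs. Optional hierarchy plants
superclusters by sharing half of each sibling's marker program. The voxel
generator builds slab-partitioned 3-D grids with region-restricted genes
(two planted energy levels plus truncated Gaussian noise; out-of-domain
voxels at −1) and the matched per-region cluster profile.

What the generator does **not** emulate: batch and sample effects,
ambient-RNA contamination gradients, cell-cycle structure, continuous
trajectories between types, gene–gene correlation beyond the planted
programs, and empty droplets. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under clean planted
structure, not their performance on tissue atlases.

## Problem sizes and numerical choices

Tests and the acceptance script run at 600–2,000 cells and 400–2,000
genes — sizes chosen so the full stack (including the O(n^2) exact
graph-t-SNE) completes in seconds to a few minutes per run while leaving
every statistical regime represented. Degenerate inputs are defined
errors: empty matrices, zero-total cells in normalization, single-cluster
enrichment, k >= n graphs, degenerate stability ranges. All tie-breaks
(incoming-edge cap, smoothing votes, top-voxel selection, dendrogram leaf
order) are deterministic and documented above; every stochastic step
(subsampling, permutation nulls, shuffles, t-SNE initialisation, Louvain)
is driven by an explicit seed, and the pipeline is bit-reproducible from
its config seed.
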