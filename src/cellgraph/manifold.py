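"""Manifold learning: informative genes, normalization, significant PCA,
balanced multiscale KNN graphs and graph-t-SNE embedding.

The stages mirror the standard graph-based workflow for UMI data:

1. select ~1000 informative genes by their positive offset from a smooth
   fit of coefficient of variation against mean expression (support-vector
   regression in log-log space); in a second pass, gene selection is driven
   by cluster enrichment instead (top 10 enriched genes per cluster);
2. normalize each cell to a common molecule total (5,000), log2(x+1)
   transform, mean-center per gene;
3. project onto the principal components that pass a Kolmogorov–Smirnov
   significance test against a column-permutation null, stopping at the
   first non-significant component;
4. build a balanced K-nearest-neighbour graph (k = 100 proposals per cell,
   at most 200 accepted incoming edges) with multiscale rank weights
   w[i, j] = 1 / rank^alpha, and its mutual (reciprocated-edge) subgraph;
5. embed with graph-t-SNE: ordinary t-SNE gradient descent whose affinity
   matrix P is the symmetrized, normalized multiscale weight matrix rather
   than perplexity-calibrated Gaussian kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVR

from .data_model import ExpressionMatrix, OUTLIER_LABEL

__all__ = [
    "ManifoldParams",
    "CellGraph",
    "select_informative_genes",
    "normalize_cells",
    "significant_components",
    "build_multiscale_knn",
    "embed_gtsne",
]


@dataclass
class ManifoldParams:
    n_genes: int = 1000
    second_pass_genes: int = 500
    genes_per_cluster: int = 10
    normalization_total: float = 5000.0
    pc_significance_alpha: float = 0.05
    max_components: int = 50
    k: int = 100
    max_incoming: int = 200
    alpha: float = 1.0
    excluded_genes: tuple = ("Xist", "Tsix")
    max_cluster_fraction_for_pca: float = 0.2

    def __post_init__(self):
        if self.k > self.max_incoming:
            raise ValueError("k must not exceed max_incoming")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class CellGraph:
    """Balanced KNN graph with multiscale weights, its mutual subgraph,
    and (once computed) the 2-D embedding."""

    knn: sp.csr_matrix
    mknn: sp.csr_matrix
    embedding: np.ndarray = None

    def __post_init__(self):
        if self.knn.shape != self.mknn.shape:
            raise ValueError("knn and mknn shapes differ")
        if (self.mknn != self.mknn.T).nnz != 0:
            raise ValueError("mknn must be symmetric")

    @property
    def n_cells(self) -> int:
        return self.knn.shape[0]


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------


def select_informative_genes(
    m: ExpressionMatrix,
    p: ManifoldParams = None,
    cluster_labels: np.ndarray = None,
) -> np.ndarray:
    """Return indices of informative genes.

    Without cluster labels: rank valid genes by the positive offset of their
    log CV from an SVR fit of log CV on log mean, return the top
    ``p.n_genes`` (sex-linked ``excluded_genes`` removed).  With labels
    (second pass): return the union of the ``genes_per_cluster`` most
    enriched genes per cluster.
    """
    p = p or ManifoldParams()
    valid_cells = np.flatnonzero(m.cell_valid)
    valid_genes = np.flatnonzero(m.gene_valid)
    symbols = m.gene_symbols
    excluded = set(p.excluded_genes)
    valid_genes = np.array(
        [g for g in valid_genes if symbols[g] not in excluded], dtype=int
    )
    if len(valid_genes) < 2:
        raise ValueError("fewer than two valid genes")

    if cluster_labels is not None:
        from .cluster_stats import EnrichmentParams, aggregate, enrichment

        sub = m.subset_cells(valid_cells)
        profile = aggregate(sub, np.asarray(cluster_labels)[valid_cells])
        enrichment(profile, EnrichmentParams())
        chosen: set[int] = set()
        vg = set(valid_genes)
        for ci in range(profile.n_clusters):
            order = np.argsort(-profile.enrichment[ci])
            picked = 0
            for g in order:
                if g in vg:
                    chosen.add(int(g))
                    picked += 1
                    if picked >= p.genes_per_cluster:
                        break
        return np.array(sorted(chosen), dtype=int)

    counts = m.counts[valid_cells][:, valid_genes]
    if sp.issparse(counts):
        mean = np.asarray(counts.mean(axis=0)).ravel()
        sq = np.asarray(counts.multiply(counts).mean(axis=0)).ravel()
    else:
        mean = counts.mean(axis=0)
        sq = (counts**2).mean(axis=0)
    var = np.maximum(sq - mean**2, 0.0)
    ok = mean > 0
    cv = np.zeros_like(mean)
    cv[ok] = np.sqrt(var[ok]) / mean[ok]
    score = np.full(len(valid_genes), -np.inf)
    fit_ok = ok & (cv > 0)
    if fit_ok.sum() >= 2:
        lx = np.log2(mean[fit_ok])[:, None]
        ly = np.log2(cv[fit_ok])
        svr = SVR(kernel="rbf", gamma="scale", C=1.0)
        svr.fit(lx, ly)
        score[fit_ok] = ly - svr.predict(lx)
    # constant genes (cv == 0) keep score −inf and are never selected
    n_take = min(p.n_genes, int(np.isfinite(score).sum()))
    order = np.argsort(-score, kind="stable")[:n_take]
    return np.sort(valid_genes[order])


def normalize_cells(
    m: ExpressionMatrix, genes: np.ndarray, p: ManifoldParams = None
) -> np.ndarray:
    """Normalize each valid cell to ``normalization_total`` molecules over
    the valid genes, log2(x+1) transform, and mean-center per gene.

    Returns a dense (valid cells) × (selected genes) matrix.
    """
    p = p or ManifoldParams()
    valid_cells = np.flatnonzero(m.cell_valid)
    totals = np.asarray(m.counts[valid_cells][:, m.gene_valid].sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = valid_cells[totals == 0]
        raise ValueError(f"cells with zero total counts: {bad.tolist()[:20]}")
    x = m.counts[valid_cells][:, genes]
    x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    x = x * (p.normalization_total / totals)[:, None]
    x = np.log2(x + 1.0)
    return x - x.mean(axis=0)


# ---------------------------------------------------------------------------
# significant principal components
# ---------------------------------------------------------------------------


def significant_components(
    x: np.ndarray,
    p: ManifoldParams = None,
    cluster_labels: np.ndarray = None,
    seed: int = 0,
):
    """Project onto the principal components that survive a KS test.

    The PCA transform is fitted on all cells, except that when
    ``cluster_labels`` are given, cells from any single cluster are capped
    at ``max_cluster_fraction_for_pca`` of the cells used for fitting (all
    cells are still projected).  Each component's cell-score distribution is
    compared (two-sample Kolmogorov–Smirnov) against the scores of a PCA
    fitted to column-permuted data; retention stops at the first component
    with p >= alpha.  If no component is significant one is retained and
    ``info["fallback"]`` is set.

    Returns ``(projection, info)`` with ``info`` carrying ``n_retained``,
    ``components`` (loadings) and ``fallback``.
    """
    p = p or ManifoldParams()
    x = np.asarray(x, dtype=float)
    n_cells, n_genes = x.shape
    if n_cells < 2:
        raise ValueError("need at least two cells")
    rng = np.random.default_rng(seed)

    fit_idx = np.arange(n_cells)
    if cluster_labels is not None:
        cluster_labels = np.asarray(cluster_labels)
        cap = max(1, int(np.ceil(p.max_cluster_fraction_for_pca * n_cells)))
        keep = []
        for c in np.unique(cluster_labels):
            idx = np.flatnonzero(cluster_labels == c)
            if len(idx) > cap:
                idx = rng.choice(idx, size=cap, replace=False)
            keep.append(idx)
        fit_idx = np.sort(np.concatenate(keep))

    n_comp = int(min(p.max_components, len(fit_idx) - 1, n_genes))
    n_comp = max(n_comp, 1)
    pca = PCA(n_components=n_comp, svd_solver="auto", random_state=seed)
    pca.fit(x[fit_idx])
    scores = pca.transform(x)

    # permutation null: shuffle each gene independently across cells
    x_null = x.copy()
    for j in range(n_genes):
        x_null[:, j] = x_null[rng.permutation(n_cells), j]
    pca_null = PCA(n_components=n_comp, svd_solver="auto", random_state=seed)
    null_scores = pca_null.fit_transform(x_null[fit_idx])

    fit_scores = scores[fit_idx]
    n_retained = 0
    for i in range(n_comp):
        stat = ks_2samp(fit_scores[:, i], null_scores[:, i])
        if stat.pvalue < p.pc_significance_alpha:
            n_retained += 1
        else:
            break
    fallback = n_retained == 0
    if fallback:
        warnings.warn("no significant components; retaining the first")
        n_retained = 1
    info = {
        "n_retained": n_retained,
        "components": pca.components_[:n_retained],
        "explained_variance": pca.explained_variance_[:n_retained],
        "fallback": fallback,
    }
    return scores[:, :n_retained], info


# ---------------------------------------------------------------------------
# balanced multiscale KNN
# ---------------------------------------------------------------------------


def build_multiscale_knn(y: np.ndarray, p: ManifoldParams = None) -> CellGraph:
    """Balanced KNN graph with multiscale weights and its mutual subgraph.

    Every cell proposes its ``k`` Euclidean nearest neighbours with weight
    1/rank^alpha (rank 1 = nearest).  Each cell accepts at most
    ``max_incoming`` incoming proposals, keeping the lowest ranks (ties
    broken by smallest proposing cell index).  The mutual graph keeps only
    edges reciprocated in the balanced graph, with the mean of the two
    directed weights.
    """
    p = p or ManifoldParams()
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    k = p.k
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(y)
    _, idx = nn.kneighbors(y)
    # drop self-neighbours (guaranteed present at distance 0)
    neigh = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k]
        neigh[i] = row
    ranks = np.tile(np.arange(1, k + 1), (n, 1))

    src = np.repeat(np.arange(n), k)
    dst = neigh.ravel()
    rnk = ranks.ravel()

    # enforce the incoming-edge cap per target, lowest (rank, source) kept
    order = np.lexsort((src, rnk, dst))
    dst_sorted = dst[order]
    starts = np.searchsorted(dst_sorted, np.arange(n))
    ends = np.searchsorted(dst_sorted, np.arange(n), side="right")
    keep = np.zeros(len(order), dtype=bool)
    for t in range(n):
        s, e = starts[t], ends[t]
        keep[s : min(e, s + p.max_incoming)] = True
    kept = order[keep]
    w = 1.0 / rnk[kept] ** p.alpha
    knn = sp.csr_matrix((w, (src[kept], dst[kept])), shape=(n, n))

    mutual_mask = knn.astype(bool).multiply(knn.astype(bool).T)
    sym_w = (knn + knn.T).multiply(mutual_mask) * 0.5
    mknn = sp.csr_matrix(sym_w)
    return CellGraph(knn=knn, mknn=mknn)


# ---------------------------------------------------------------------------
# graph t-SNE
# ---------------------------------------------------------------------------


def embed_gtsne(
    g: CellGraph,
    seed: int = 0,
    n_iter: int = 350,
    early_exaggeration: float = 12.0,
    early_iter: int = 100,
    learning_rate: float = None,
) -> np.ndarray:
    """Embed the multiscale KNN graph in 2-D with graph-t-SNE.

    Standard t-SNE gradient descent (Student-t low-dimensional kernel,
    early exaggeration, momentum 0.5 -> 0.8) is run with the affinity
    matrix P = (W + W^T) / (2 * sum(W)) built from the multiscale weights,
    in place of perplexity-calibrated Gaussian affinities.  Deterministic
    given the seed.  Disconnected graphs are embedded anyway (components
    place themselves independently) with a warning.
    """
    W = g.knn
    n = W.shape[0]
    n_comp, _ = sp.csgraph.connected_components(W, directed=False)
    if n_comp > 1:
        warnings.warn(f"graph has {n_comp} connected components")
    P = np.asarray((W + W.T).todense(), dtype=np.float64)
    np.fill_diagonal(P, 0.0)
    total = P.sum()
    if total == 0:
        raise ValueError("graph has no edges")
    P /= total
    P = np.maximum(P, 1e-12)

    rng = np.random.default_rng(seed)
    Y = rng.normal(0.0, 1e-4, size=(n, 2))
    if learning_rate is None:
        learning_rate = max(n / early_exaggeration / 4.0, 50.0)
    gains = np.ones_like(Y)
    update = np.zeros_like(Y)
    Pe = P * early_exaggeration
    for it in range(n_iter):
        momentum = 0.5 if it < early_iter else 0.8
        Pcur = Pe if it < early_iter else P
        sq = (Y**2).sum(axis=1)
        D = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
        num = 1.0 / (1.0 + D)
        np.fill_diagonal(num, 0.0)
        Q = num / num.sum()
        PQ = (Pcur - Q) * num
        grad = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
        inc = np.sign(grad) != np.sign(update)
        gains[inc] += 0.2
        gains[~inc] *= 0.8
        np.clip(gains, 0.01, None, out=gains)
        update = momentum * update - learning_rate * gains * grad
        Y += update
        Y -= Y.mean(axis=0)
    g.embedding = Y
    return Y
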