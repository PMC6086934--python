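"""Polished Louvain clustering and cluster-robustness assessment.

Louvain community detection on the mutual KNN graph resolves most cell
populations, but modularity optimisation has a resolution limit: genuinely
distinct small populations get absorbed into larger communities.  The
polish exploits the 2-D graph embedding: cells are marked outliers by three
rules (tiny clusters, DBSCAN noise in the embedding, or disagreement with
their graph neighbourhood), then every cluster is screened in its own
standardized 2-D frame and re-partitioned by DBSCAN when it shows internal
density structure.  Finally labels are smoothed by a 10-nearest-neighbour
majority vote and undersized clusters re-marked as outliers.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import DBSCAN
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .data_model import ExpressionMatrix, OUTLIER_LABEL
from .manifold import CellGraph

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "polished_louvain",
    "smooth_labels",
    "assess_robustness",
]


@dataclass
class ClusterParams:
    louvain_resolution: float = 1.0
    min_cluster_size: int = 10
    outlier_neighbor_fraction: float = 0.8
    mad_threshold: float = 3.5
    mad_min_outliers: int = 3
    outlier_eps_percentile: float = 80.0
    split_eps_percentile: float = 70.0
    split_min_fraction: float = 0.05
    split_min_cells: int = 25
    smoothing_k: int = 10
    kth_neighbor: int = None  # defaults to min(5 * smoothing_k, 50)
    seed: int = 0

    def __post_init__(self):
        for v in (self.outlier_eps_percentile, self.split_eps_percentile):
            if not 0.0 < v < 100.0:
                raise ValueError("percentiles must lie in (0, 100)")
        for v in (self.outlier_neighbor_fraction, self.split_min_fraction):
            if not 0.0 < v < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if self.kth_neighbor is None:
            self.kth_neighbor = min(5 * self.smoothing_k, 50)


@dataclass
class ClusterResult:
    """Per-cell integer labels with −1 as the outlier sentinel."""

    labels: np.ndarray
    provenance: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.provenance is None:
            self.provenance = np.array([""] * len(self.labels), dtype=object)
        valid = self.labels[self.labels != OUTLIER_LABEL]
        if len(valid) and (sorted(set(valid)) != list(range(valid.max() + 1))):
            raise ValueError("cluster labels must be consecutive from 0")

    @property
    def n_clusters(self) -> int:
        labs = self.labels[self.labels != OUTLIER_LABEL]
        return 0 if len(labs) == 0 else int(labs.max()) + 1

    def sizes(self) -> np.ndarray:
        return np.bincount(
            self.labels[self.labels != OUTLIER_LABEL], minlength=self.n_clusters
        )


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Renumber non-outlier labels 0..n−1 by decreasing cluster size."""
    out = np.full(len(labels), OUTLIER_LABEL, dtype=int)
    ids, counts = np.unique(labels[labels != OUTLIER_LABEL], return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    for new, old in enumerate(order):
        out[labels == old] = new
    return out


def _louvain(mknn: sp.spmatrix, resolution: float, seed: int) -> np.ndarray:
    coo = sp.triu(mknn, k=1).tocoo()
    g = igraph.Graph(
        n=mknn.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    _pyrandom.seed(seed)  # igraph draws its randomness from Python's RNG
    part = g.community_multilevel(weights="weight", resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def _kth_nn_distance(xy: np.ndarray, k: int) -> np.ndarray:
    k = min(k, len(xy) - 1)
    if k < 1:
        return np.zeros(len(xy))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(xy)
    dist, _ = nn.kneighbors(xy)
    return dist[:, -1]


def polished_louvain(g: CellGraph, p: ClusterParams = None) -> ClusterResult:
    """Louvain on the mutual KNN graph followed by outlier rejection,
    density-based cluster splitting in the 2-D embedding, and majority
    smoothing.  Clusters are only relabelled to outlier or split, never
    merged."""
    p = p or ClusterParams()
    if g.embedding is None:
        raise ValueError("graph has no embedding; run embed_gtsne first")
    xy = np.asarray(g.embedding, dtype=float)
    n = g.n_cells
    labels = _renumber(_louvain(g.mknn, p.louvain_resolution, p.seed))
    provenance = np.array([""] * n, dtype=object)

    # --- outlier rules -----------------------------------------------------
    sizes = np.bincount(labels, minlength=labels.max() + 1)
    small = sizes[labels] < p.min_cluster_size
    provenance[small] = "small_cluster"

    kth = _kth_nn_distance(xy, p.kth_neighbor)
    eps = np.percentile(kth, p.outlier_eps_percentile)
    db = DBSCAN(eps=eps, min_samples=10).fit(xy)
    noise = db.labels_ == -1
    provenance[noise & ~small] = "dbscan_noise"

    neigh_frac = _foreign_neighbor_fraction(g, labels, p.smoothing_k)
    foreign = neigh_frac > p.outlier_neighbor_fraction
    provenance[foreign & ~small & ~noise] = "foreign_neighbors"

    outlier = small | noise | foreign
    labels = labels.copy()
    labels[outlier] = OUTLIER_LABEL

    # --- per-cluster splitting in the standardized embedding ---------------
    labels = _split_clusters(labels, xy, p)

    # --- smoothing, then one re-check of the size invariant ----------------
    labels = smooth_labels(labels, g, p.smoothing_k)
    sizes = np.bincount(
        labels[labels != OUTLIER_LABEL], minlength=max(labels.max() + 1, 1)
    )
    for c in np.flatnonzero(sizes < p.min_cluster_size):
        undersized = labels == c
        labels[undersized] = OUTLIER_LABEL
        provenance[undersized] = "post_smoothing_small"
    labels = _renumber(labels)
    provenance[labels == OUTLIER_LABEL] = np.where(
        provenance[labels == OUTLIER_LABEL] == "",
        "outlier",
        provenance[labels == OUTLIER_LABEL],
    )
    return ClusterResult(labels=labels, provenance=provenance)


def _foreign_neighbor_fraction(g: CellGraph, labels, k) -> np.ndarray:
    frac = np.zeros(g.n_cells)
    knn = g.knn
    for i in range(g.n_cells):
        row = knn.getrow(i)
        if row.nnz == 0:
            continue
        order = np.argsort(-row.data)[:k]  # highest weight = lowest rank
        neigh = row.indices[order]
        frac[i] = np.mean(labels[neigh] != labels[i])
    return frac


def _split_clusters(labels: np.ndarray, xy: np.ndarray, p: ClusterParams):
    """Standardize each cluster in 2-D and re-partition it by DBSCAN when it
    shows MAD outliers or a heavy tail of isolated cells."""
    labels = labels.copy()
    next_label = labels.max() + 1
    for c in np.unique(labels[labels != OUTLIER_LABEL]):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2 * p.min_cluster_size:
            continue
        sub = xy[idx] - xy[idx].mean(axis=0)
        # PCA-align, then standardize each axis
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        sub = sub @ vt.T
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        sub = sub / sd

        med = np.median(sub, axis=0)
        mad = np.median(np.abs(sub - med), axis=0)
        mad[mad == 0] = 1e-12
        mod_z = 0.6745 * np.abs(sub - med) / mad
        n_mad_out = int((mod_z.max(axis=1) > p.mad_threshold).sum())

        kth = _kth_nn_distance(sub, p.kth_neighbor)
        eps70 = np.percentile(kth, p.split_eps_percentile)
        min_pts = max(int(np.ceil(p.split_min_fraction * len(idx))), p.split_min_cells)
        n_far = int((kth > eps70).sum())

        if n_mad_out < p.mad_min_outliers and n_far <= min_pts:
            continue
        db = DBSCAN(eps=eps70, min_samples=min_pts).fit(sub)
        parts = db.labels_
        found = np.unique(parts[parts != -1])
        if len(found) <= 1 and (parts != -1).all():
            continue  # DBSCAN saw a single dense component, no change
        for pi, part in enumerate(found):
            labels[idx[parts == part]] = c if pi == 0 else next_label
            if pi > 0:
                next_label += 1
        labels[idx[parts == -1]] = OUTLIER_LABEL
    return labels


def smooth_labels(labels: np.ndarray, g: CellGraph, k: int = 10) -> np.ndarray:
    """Majority vote over each cell's k nearest graph neighbours (by rank).

    The outlier sentinel participates as an ordinary label; ties go to the
    smaller label id (with −1 ordered last, so real clusters win ties
    against the outlier label).
    """
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    knn = g.knn
    for i in range(g.n_cells):
        row = knn.getrow(i)
        if row.nnz == 0:
            continue
        avail = min(k, row.nnz)
        if row.nnz < k:
            warnings.warn(f"cell {i} has only {row.nnz} neighbours; using all")
        order = np.argsort(-row.data)[:avail]
        neigh_labels = labels[row.indices[order]]
        ids, votes = np.unique(neigh_labels, return_counts=True)
        # ties: smallest non-outlier label wins; −1 sorts after real labels
        key = np.where(ids == OUTLIER_LABEL, np.iinfo(np.int32).max, ids)
        best = ids[np.lexsort((key, -votes))][0]
        out[i] = best
    return out


def assess_robustness(
    m: ExpressionMatrix,
    clusters: ClusterResult,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    n_estimators: int = 100,
):
    """Train a random-forest on 80% of clustered cells and report, on the
    held-out 20%, the mean assigned probability of every cluster for test
    cells of each true cluster, plus per-cluster precision/recall.

    Returns ``(prob_matrix, report)`` as DataFrames; prob_matrix rows are
    true clusters, columns predicted clusters, rows summing to 1.
    """
    labels = clusters.labels
    keep = labels != OUTLIER_LABEL
    if len(np.unique(labels[keep])) < 2:
        raise ValueError("robustness assessment needs at least two clusters")
    counts = m.counts[np.flatnonzero(keep)]
    x = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    totals = x.sum(axis=1)
    totals[totals == 0] = 1.0
    x = np.log2(x * (5000.0 / totals[:, None]) + 1.0)
    y = labels[keep]
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(x_tr, y_tr)
    proba = rf.predict_proba(x_te)
    pred = rf.classes_[np.argmax(proba, axis=1)]
    ids = rf.classes_
    prob_matrix = pd.DataFrame(
        [proba[y_te == c].mean(axis=0) for c in ids], index=ids, columns=ids
    )
    rows = []
    for c in ids:
        tp = np.sum((pred == c) & (y_te == c))
        prec = tp / max(np.sum(pred == c), 1)
        rec = tp / max(np.sum(y_te == c), 1)
        rows.append({"cluster": c, "precision": prec, "recall": rec})
    return prob_matrix, pd.DataFrame(rows).set_index("cluster")
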