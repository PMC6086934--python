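"""Cluster-level statistics: aggregation, enrichment, trinarization.

The enrichment score of gene *j* in cluster *i* is

    E[i, j] = ((f[i,j] + eps1) / (f_out[i,j] + eps1))
            * ((mu[i,j] + eps2) / (mu_out[i,j] + eps2))

where ``f`` is the in-cluster detection fraction, ``mu`` the in-cluster mean
count, and ``f_out`` / ``mu_out`` the same quantities over all other
clustered cells.  The small constants eps1 = 0.1 and eps2 = 0.01 keep the
score finite as the out-of-cluster statistics go to zero.  Permutation
q-values are obtained by shuffling cluster labels across cells.

Trinarization calls a gene *expressed*, *not expressed* or *indeterminate*
in a cluster from a beta-binomial model: with the gene detected in k of the
cluster's n cells and a Beta(a, b) prior on the population detection
frequency theta, the posterior is theta | n,k ~ Beta(a+k, b+n−k) and

    P(theta > f) = 1 − I_f(a + k, b + n − k)

with I the regularized incomplete beta function, evaluated in stable
log-space form.  The call is *expressed* when P > 1 − PEP and
*not expressed* when P < PEP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import betaincc

from .data_model import ClusterProfile, ExpressionMatrix, OUTLIER_LABEL

__all__ = [
    "EnrichmentParams",
    "TrinarizationParams",
    "aggregate",
    "enrichment",
    "trinarize",
    "trinarize_profile",
]


@dataclass
class EnrichmentParams:
    eps_fraction: float = 0.1
    eps_mean: float = 0.01
    n_shuffles: int = 100

    def __post_init__(self):
        if self.eps_fraction <= 0 or self.eps_mean <= 0:
            raise ValueError("regularizing constants must be positive")


@dataclass
class TrinarizationParams:
    """Beta-binomial prior and calling thresholds (a=1.5, b=2, f=0.2, PEP=0.05)."""

    a: float = 1.5
    b: float = 2.0
    f: float = 0.2
    pep: float = 0.05

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior shapes must be positive")
        if not 0.0 < self.f < 1.0:
            raise ValueError("f must lie in (0, 1)")
        if not 0.0 < self.pep < 0.5:
            raise ValueError("pep must lie in (0, 0.5)")


def _cluster_indicator(labels: np.ndarray, cluster_ids: np.ndarray) -> sp.csr_matrix:
    """One-hot clusters × cells matrix over non-outlier cells."""
    n_cells = len(labels)
    pos = {c: i for i, c in enumerate(cluster_ids)}
    rows, cols = [], []
    for j, lab in enumerate(labels):
        if lab in pos:
            rows.append(pos[lab])
            cols.append(j)
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(len(cluster_ids), n_cells))


def aggregate(m: ExpressionMatrix, labels: np.ndarray) -> ClusterProfile:
    """Aggregate a clustered matrix into per-cluster mean counts and
    detection fractions; outlier cells (label −1) are excluded."""
    labels = np.asarray(labels)
    if len(labels) != m.n_cells:
        raise ValueError("label vector length does not match cell count")
    cluster_ids = np.unique(labels[labels != OUTLIER_LABEL])
    if len(cluster_ids) == 0:
        raise ValueError("all cells are outliers; nothing to aggregate")
    ind = _cluster_indicator(labels, cluster_ids)
    counts = m.counts if sp.issparse(m.counts) else sp.csr_matrix(m.counts)
    n_per = np.asarray(ind.sum(axis=1)).ravel()
    sums = np.asarray((ind @ counts).todense())
    nnz = np.asarray((ind @ (counts > 0).astype(np.int64)).todense())
    return ClusterProfile(
        mean_expr=sums / n_per[:, None],
        nonzero_frac=nnz / n_per[:, None],
        cell_counts=n_per.astype(int),
        gene_symbols=m.gene_symbols,
        cluster_ids=cluster_ids,
        nonzero_counts=nnz,
    )


def _enrichment_from_stats(f, mu, n, p: EnrichmentParams):
    """E given per-cluster stats; the complement is the other clusters' cells."""
    n = np.asarray(n, dtype=float)
    total = n.sum()
    n_out = total - n
    sum_mu = (mu * n[:, None]).sum(axis=0)
    sum_nnz = (f * n[:, None]).sum(axis=0)
    mu_out = (sum_mu[None, :] - mu * n[:, None]) / n_out[:, None]
    f_out = (sum_nnz[None, :] - f * n[:, None]) / n_out[:, None]
    return ((f + p.eps_fraction) / (f_out + p.eps_fraction)) * (
        (mu + p.eps_mean) / (mu_out + p.eps_mean)
    )


def enrichment(
    profile: ClusterProfile,
    p: EnrichmentParams = None,
    seed: int = 0,
    matrix: ExpressionMatrix = None,
    labels: np.ndarray = None,
) -> ClusterProfile:
    """Fill the enrichment (and, when cell data is given, q-value) layers.

    q-values require re-aggregating under permuted cluster labels, so the
    cell-level ``matrix`` and ``labels`` must be supplied to compute them;
    with a profile alone only the scores are filled.  q is the add-one
    permutation estimate (1 + #{E_perm >= E_obs}) / (1 + n_shuffles).
    """
    p = p or EnrichmentParams()
    if profile.n_clusters < 2:
        raise ValueError("enrichment needs at least two clusters")
    E = _enrichment_from_stats(
        profile.nonzero_frac, profile.mean_expr, profile.cell_counts, p
    )
    profile.enrichment = E
    if matrix is not None and labels is not None:
        rng = np.random.default_rng(seed)
        labels = np.asarray(labels)
        clustered = labels != OUTLIER_LABEL
        exceed = np.zeros_like(E, dtype=np.int64)
        for _ in range(p.n_shuffles):
            perm = labels.copy()
            perm[clustered] = rng.permutation(labels[clustered])
            pprof = aggregate(matrix, perm)
            Ep = _enrichment_from_stats(
                pprof.nonzero_frac, pprof.mean_expr, pprof.cell_counts, p
            )
            exceed += Ep >= E
        profile.enrichment_q = (1.0 + exceed) / (1.0 + p.n_shuffles)
    return profile


def trinarize(k, n, p: TrinarizationParams = None):
    """Posterior probability P(theta > f) and expression call.

    ``k`` (detected cells) and ``n`` (cluster size) may be scalars or
    arrays.  Returns ``(P, call)`` with call in {"expressed",
    "not_expressed", "indeterminate"} (elementwise for arrays).
    """
    p = p or TrinarizationParams()
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    # betaincc evaluates the upper regularized incomplete beta in log space
    prob = betaincc(p.a + k, p.b + n - k, p.f)
    call = np.where(
        prob > 1.0 - p.pep,
        "expressed",
        np.where(prob < p.pep, "not_expressed", "indeterminate"),
    )
    if prob.ndim == 0:
        return float(prob), str(call)
    return prob, call


def trinarize_profile(
    profile: ClusterProfile, p: TrinarizationParams = None
) -> ClusterProfile:
    """Fill the ``trinaries`` layer (posterior P per cluster × gene)."""
    p = p or TrinarizationParams()
    if profile.nonzero_counts is not None:
        k = profile.nonzero_counts
    else:
        k = np.rint(profile.nonzero_frac * profile.cell_counts[:, None])
    n = np.broadcast_to(profile.cell_counts[:, None], k.shape)
    prob, _ = trinarize(k, n, p)
    profile.trinaries = prob
    return profile
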