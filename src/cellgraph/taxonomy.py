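"""Cell-type taxonomy: dendrogram construction and its stability test.

The dendrogram is built over cluster expression profiles with a
gene-exclusion scheme designed to suppress technical artifacts:

1. *pan-enriched* genes of each non-neuronal class are found by a
   trinarization criterion (the fraction of the class's clusters with
   posterior ~1 at f = 0.05 exceeds the fraction of neuronal clusters
   with posterior > 0.9);
2. pan-enriched, ambient-RNA and immediate-early genes are zeroed within
   neuronal clusters; sex-linked genes and Egr1/Jun are removed everywhere;
3. each cluster profile is bounded to its top 5,000 detected genes and
   rescaled to a total of 10,000;
4. the top N = 28 enriched genes per cluster are pooled; an initial
   Ward/Euclidean tree on log2(x+1) profiles is cut at distance 50 and each
   coarse group contributes 1.5 N additional top genes by within-group
   enrichment;
5. the final tree is agglomerated with correlation distance and Ward
   linkage on the selected gene subspace.

The stability test rebuilds the tree for N in 10..44 and reports, per
branch of the reference tree (N = 28), the fraction of N values for which
a corresponding branch (maximum Jaccard leaf overlap) satisfies (1) >= 90%
leaf overlap or (2) an identical leaf set in identical canonical order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .data_model import ClusterProfile

__all__ = ["TaxonomyParams", "Taxonomy", "build_dendrogram", "stability_test"]

SEX_GENES = ("Xist", "Tsix", "Eif2s3y", "Ddx3y", "Uty", "Kdm5d")
IEG_ALL = ("Egr1", "Jun")
IEG_NEURON_MASK = ("Fos", "Jun", "Junb", "Egr1")
AMBIENT_GENES = ("Trf", "Plp1", "Mog", "Mobp", "Mfge8", "Mbp", "Hbb-bs", "H2-DMb2")


@dataclass
class TaxonomyParams:
    top_genes_per_cluster: int = 28
    stability_n_min: int = 10
    stability_n_max: int = 44
    detected_gene_bound: int = 5000
    profile_total: float = 10000.0
    coarse_cut_distance: float = 50.0
    second_round_gene_factor: float = 1.5
    sex_genes: tuple = SEX_GENES
    ieg_genes: tuple = IEG_ALL
    ieg_neuron_genes: tuple = IEG_NEURON_MASK
    ambient_genes: tuple = AMBIENT_GENES
    neuron_class: str = "neurons"
    masking: bool = True

    def __post_init__(self):
        if self.stability_n_min >= self.stability_n_max:
            raise ValueError("degenerate stability N range")


@dataclass
class Taxonomy:
    """Binary merge tree over clusters (scipy linkage encoding)."""

    linkage: np.ndarray
    cluster_ids: np.ndarray
    selected_genes: np.ndarray
    stability: pd.DataFrame = None

    @property
    def n_leaves(self) -> int:
        return len(self.cluster_ids)

    def cut(self, n_groups: int) -> np.ndarray:
        """Leaf group assignment at an n-group cut of the tree."""
        return fcluster(self.linkage, t=n_groups, criterion="maxclust")

    def branches(self) -> list[frozenset]:
        """Leaf sets of all internal nodes (root included)."""
        node, _ = to_tree(self.linkage, rd=True)
        out = []

        def rec(nd):
            if nd.is_leaf():
                return [nd.id]
            leaves = rec(nd.left) + rec(nd.right)
            out.append(frozenset(leaves))
            return leaves

        rec(node)
        return out

    def canonical_orders(self) -> dict[frozenset, tuple]:
        """Branch leaf set -> leaf order with children sorted by
        (subtree size, smallest leaf id); makes leaf order well-defined."""
        node = to_tree(self.linkage)
        orders: dict[frozenset, tuple] = {}

        def rec(nd):
            if nd.is_leaf():
                return (nd.id,)
            parts = sorted(
                (rec(nd.left), rec(nd.right)), key=lambda t: (len(t), min(t))
            )
            order = parts[0] + parts[1]
            orders[frozenset(order)] = order
            return order

        rec(node)
        return orders

    def to_newick(self) -> str:
        node = to_tree(self.linkage)
        names = [str(c) for c in self.cluster_ids]

        def rec(nd, parent_height):
            length = max(parent_height - nd.dist, 0.0)
            if nd.is_leaf():
                return f"{names[nd.id]}:{length:.6g}"
            return (
                f"({rec(nd.left, nd.dist)},{rec(nd.right, nd.dist)}):{length:.6g}"
            )

        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


# ---------------------------------------------------------------------------


def _pan_enriched_genes(
    profile: ClusterProfile, classes: np.ndarray, p: TaxonomyParams
) -> np.ndarray:
    """Genes pan-enriched in any non-neuronal class versus neurons, judged
    on the f = 0.05 trinarization posterior."""
    from .cluster_stats import TrinarizationParams, trinarize

    params = TrinarizationParams(f=0.05)
    if profile.nonzero_counts is not None:
        k = np.asarray(profile.nonzero_counts, dtype=float)
    else:
        k = np.rint(profile.nonzero_frac * profile.cell_counts[:, None])
    n = np.broadcast_to(profile.cell_counts[:, None].astype(float), k.shape)
    post, _ = trinarize(k, n, params)

    neurons = classes == p.neuron_class
    pan = np.zeros(profile.n_genes, dtype=bool)
    if neurons.sum() == 0 or neurons.all():
        return pan
    frac_neuron_hi = (post[neurons] > 0.9).mean(axis=0)
    for cls in np.unique(classes[~neurons]):
        members = classes == cls
        frac_one = (post[members] > 0.999).mean(axis=0)
        pan |= frac_one > frac_neuron_hi
    return pan


def _masked_profile(
    profile: ClusterProfile, classes: np.ndarray, p: TaxonomyParams
) -> np.ndarray:
    x = np.asarray(profile.mean_expr, dtype=float).copy()
    symbols = profile.gene_symbols
    sym_idx = {s: i for i, s in enumerate(symbols)}

    if p.masking:
        neurons = classes == p.neuron_class
        mask_neuronal = _pan_enriched_genes(profile, classes, p)
        for g in tuple(p.ambient_genes) + tuple(p.ieg_neuron_genes):
            if g in sym_idx:
                mask_neuronal[sym_idx[g]] = True
        missing = [
            g
            for g in tuple(p.ambient_genes) + tuple(p.ieg_neuron_genes)
            + tuple(p.sex_genes) + tuple(p.ieg_genes)
            if g not in sym_idx
        ]
        if missing:
            warnings.warn(f"masking genes absent from the profile: {missing}")
        if neurons.any():
            x[np.ix_(neurons, np.flatnonzero(mask_neuronal))] = 0.0
        for g in tuple(p.sex_genes) + tuple(p.ieg_genes):
            if g in sym_idx:
                x[:, sym_idx[g]] = 0.0

    # bound to the top detected genes per cluster, then rescale totals
    if x.shape[1] > p.detected_gene_bound:
        for i in range(x.shape[0]):
            order = np.argsort(-x[i], kind="stable")
            x[i, order[p.detected_gene_bound :]] = 0.0
    totals = x.sum(axis=1)
    totals[totals == 0] = 1.0
    return x * (p.profile_total / totals[:, None])


def _select_genes(x: np.ndarray, enr: np.ndarray, n_top: int, p: TaxonomyParams):
    """Pool top enriched genes per cluster, then add per coarse group."""
    n_clusters = x.shape[0]
    selected: set[int] = set()
    for i in range(n_clusters):
        selected.update(np.argsort(-enr[i], kind="stable")[:n_top].tolist())
    sel = np.array(sorted(selected), dtype=int)

    logx = np.log2(x + 1.0)
    if n_clusters > 2:
        z = linkage(logx[:, sel], method="ward", metric="euclidean")
        coarse = fcluster(z, t=p.coarse_cut_distance, criterion="distance")
        n_extra = int(round(p.second_round_gene_factor * n_top))
        col_total = x.sum(axis=0) + 1e-12
        for grp in np.unique(coarse):
            members = coarse == grp
            grp_enr = x[members].mean(axis=0) / col_total
            selected.update(np.argsort(-grp_enr, kind="stable")[:n_extra].tolist())
    return np.array(sorted(selected), dtype=int)


def _build(x, enr, n_top, p):
    sel = _select_genes(x, enr, n_top, p)
    logx = np.log2(x[:, sel] + 1.0)
    d = pdist(logx, metric="correlation")
    if not np.all(np.isfinite(d)):
        d = np.nan_to_num(d, nan=1.0)
    with warnings.catch_warnings():
        # Ward on a non-Euclidean (correlation) distance is intentional;
        # possible height inversions are permitted, not repaired
        warnings.simplefilter("ignore")
        z = linkage(d, method="ward")
    return z, sel


def build_dendrogram(
    profile: ClusterProfile,
    classes: np.ndarray = None,
    p: TaxonomyParams = None,
) -> Taxonomy:
    """Build the cluster taxonomy (see module docstring).

    ``classes`` carries the per-cluster major-class label; when omitted all
    clusters are treated as neuronal (no pan-enrichment masking possible).
    """
    p = p or TaxonomyParams()
    if profile.enrichment is None:
        raise ValueError("profile lacks enrichment scores")
    if classes is None:
        classes = np.array([p.neuron_class] * profile.n_clusters)
    classes = np.asarray(classes)
    if profile.n_clusters == 1:
        return Taxonomy(
            linkage=np.zeros((0, 4)),
            cluster_ids=profile.cluster_ids,
            selected_genes=np.arange(profile.n_genes),
        )
    x = _masked_profile(profile, classes, p)
    enr = np.asarray(profile.enrichment, dtype=float)
    z, sel = _build(x, enr, p.top_genes_per_cluster, p)
    if len(sel) < p.top_genes_per_cluster:
        raise ValueError("fewer selected genes than top_genes_per_cluster")
    return Taxonomy(
        linkage=z,
        cluster_ids=profile.cluster_ids,
        selected_genes=profile.gene_symbols[sel],
    )


def stability_test(
    profile: ClusterProfile,
    classes: np.ndarray = None,
    p: TaxonomyParams = None,
    reference: Taxonomy = None,
) -> pd.DataFrame:
    """Per-branch stability of the reference tree across the N range.

    For each N in [stability_n_min, stability_n_max] the tree is rebuilt;
    each reference branch is matched to the test branch with maximal
    Jaccard leaf overlap.  Criterion 1: Jaccard >= 0.9; criterion 2:
    identical leaf set in identical canonical order.  Returns a table with
    the per-branch satisfied fractions.
    """
    p = p or TaxonomyParams()
    if classes is None:
        classes = np.array([p.neuron_class] * profile.n_clusters)
    if reference is None:
        reference = build_dendrogram(profile, classes, p)
    ref_branches = reference.branches()
    ref_orders = reference.canonical_orders()

    crit1 = {b: 0 for b in ref_branches}
    crit2 = {b: 0 for b in ref_branches}
    n_values = list(range(p.stability_n_min, p.stability_n_max + 1))
    x = _masked_profile(profile, np.asarray(classes), p)
    enr = np.asarray(profile.enrichment, dtype=float)
    for n_top in n_values:
        z, _ = _build(x, enr, n_top, p)
        test = Taxonomy(z, reference.cluster_ids, np.array([]))
        test_branches = test.branches()
        test_orders = test.canonical_orders()
        for b in ref_branches:
            jac = max(
                (len(b & tb) / len(b | tb) for tb in test_branches), default=0.0
            )
            if jac >= 0.9:
                crit1[b] += 1
            if b in test_orders and test_orders[b] == ref_orders[b]:
                crit2[b] += 1

    rows = []
    for b in ref_branches:
        rows.append(
            {
                "branch": tuple(sorted(b)),
                "n_leaves": len(b),
                "p_overlap": crit1[b] / len(n_values),
                "p_identical": crit2[b] / len(n_values),
            }
        )
    table = pd.DataFrame(rows)
    reference.stability = table
    return table
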