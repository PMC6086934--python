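"""Synthetic single-cell data with planted structure.

Emulates droplet scRNA-seq UMI count matrices: negative-binomial counts with
planted cluster structure and marker genes, planted doublets (sums of two
cells' expected profiles), planted low-quality cells (downsampled below the
600-UMI QC threshold), and optionally a planted hierarchy in which sibling
clusters share part of their marker program.  A companion generator builds a
3-D voxel expression atlas with region-restricted genes plus the matched
cluster profile, mirroring a coarse in-situ hybridisation energy grid.

Ground truth (cluster identity, doublet and low-quality flags) is returned
alongside the data so that every downstream stage can be scored without any
external input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, ClusterProfile

__all__ = [
    "SimulationDesign",
    "DesignError",
    "generate_counts",
    "generate_voxel_atlas",
    "slab_regions",
]


class DesignError(ValueError):
    """A simulation design violates its own constraints."""


@dataclass
class SimulationDesign:
    """Parameters of a planted-structure count simulation.

    The defaults describe the standard study condition used throughout the
    test-bench: 2,000 cells in 8 equally sized, well-separated clusters over
    2,000 genes, 10 private marker genes per cluster (detected in ~10% of
    cells at baseline, 30-fold elevated in the home cluster), moderate
    negative-binomial overdispersion, 2% doublets and 2% low-quality cells.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    n_clusters: int = 8
    cluster_proportions: np.ndarray | None = None
    marker_genes_per_cluster: int = 10
    marker_fold_change: float = 30.0
    nb_dispersion: float = 0.15
    baseline_mean: float = 1.0
    mean_sigma: float = 1.8
    mean_total_umis: float = 2000.0
    marker_baseline_detection: float = 0.1
    doublet_rate: float = 0.02
    lowq_rate: float = 0.02
    hierarchy: list[list[int]] | None = None
    shared_marker_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_clusters <= 0:
            raise DesignError("cell, gene and cluster counts must be positive")
        if self.cluster_proportions is None:
            self.cluster_proportions = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_proportions = np.asarray(self.cluster_proportions, dtype=float)
        if len(self.cluster_proportions) != self.n_clusters:
            raise DesignError("cluster_proportions length != n_clusters")
        if not np.isclose(self.cluster_proportions.sum(), 1.0):
            raise DesignError("cluster_proportions must sum to 1")
        for name in ("doublet_rate", "lowq_rate", "shared_marker_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must lie in [0, 1]")
        if self.marker_fold_change <= 0 or self.nb_dispersion <= 0:
            raise DesignError("fold change and dispersion must be positive")
        n_marker = self.marker_genes_per_cluster * self.n_clusters
        if self.hierarchy is not None:
            flat = [c for grp in self.hierarchy for c in grp]
            if sorted(flat) != list(range(self.n_clusters)):
                raise DesignError("hierarchy must partition the clusters")
            n_marker += sum(
                int(round(self.shared_marker_fraction * self.marker_genes_per_cluster))
                for _ in self.hierarchy
            )
        if n_marker > self.n_genes:
            raise DesignError(
                f"{n_marker} marker genes requested but only "
                f"{self.n_genes} genes in the design"
            )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB(mean, dispersion) with var = mean + dispersion * mean**2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def generate_counts(design: SimulationDesign):
    """Simulate a UMI count matrix with planted structure.

    Returns ``(matrix, truth)`` where ``truth`` is a per-cell DataFrame with
    columns ``cluster`` (−1 for doublets), ``is_doublet``, ``is_low_quality``
    and ``class_label``, plus per-gene marker assignments in
    ``truth.attrs["marker_genes"]`` (cluster → gene index array).
    """
    d = design
    rng = np.random.default_rng(d.seed)

    # per-gene baseline means, log-normal around baseline_mean, rescaled so
    # the expected per-cell depth matches mean_total_umis (depth is a
    # property of the assay, not of the gene panel size)
    gene_means = d.baseline_mean * rng.lognormal(
        -0.5 * d.mean_sigma**2, d.mean_sigma, d.n_genes
    )
    if d.mean_total_umis is not None:
        gene_means *= d.mean_total_umis / gene_means.sum()
    # marker genes are anchored at a moderate baseline: canonical cell-type
    # markers are reliably detected genes, not ones at the noise floor.
    # The anchor is the NB mean whose out-of-cluster detection fraction is
    # marker_baseline_detection: P(X > 0) = 1 - (1 + phi*m)^(-1/phi).
    n_marker_total = d.marker_genes_per_cluster * d.n_clusters
    if d.hierarchy is not None:
        n_marker_total += len(d.hierarchy) * int(
            round(d.shared_marker_fraction * d.marker_genes_per_cluster)
        )
    phi = d.nb_dispersion
    m_star = ((1.0 - d.marker_baseline_detection) ** (-phi) - 1.0) / phi
    gene_means[:n_marker_total] = m_star

    # assign marker genes: private per cluster, then shared per hierarchy group
    marker_genes: dict[int, np.ndarray] = {}
    cursor = 0
    for j in range(d.n_clusters):
        marker_genes[j] = np.arange(cursor, cursor + d.marker_genes_per_cluster)
        cursor += d.marker_genes_per_cluster
    shared_genes: dict[int, np.ndarray] = {}
    if d.hierarchy is not None:
        n_shared = int(round(d.shared_marker_fraction * d.marker_genes_per_cluster))
        for gi, _grp in enumerate(d.hierarchy):
            shared_genes[gi] = np.arange(cursor, cursor + n_shared)
            cursor += n_shared

    # cluster expected-expression profiles
    profiles = np.tile(gene_means, (d.n_clusters, 1))
    for j in range(d.n_clusters):
        profiles[j, marker_genes[j]] *= d.marker_fold_change
    if d.hierarchy is not None:
        for gi, grp in enumerate(d.hierarchy):
            for j in grp:
                profiles[j, shared_genes[gi]] *= d.marker_fold_change

    clusters = rng.choice(d.n_clusters, size=d.n_cells, p=d.cluster_proportions)
    is_doublet = rng.random(d.n_cells) < d.doublet_rate
    is_lowq = (rng.random(d.n_cells) < d.lowq_rate) & ~is_doublet

    mean_matrix = profiles[clusters].copy()
    # doublets: sum of the expected profiles of two random cells
    partner = rng.choice(d.n_clusters, size=d.n_cells, p=d.cluster_proportions)
    mean_matrix[is_doublet] += profiles[partner[is_doublet]]

    counts = _nb_sample(rng, mean_matrix, d.nb_dispersion).astype(np.int64)

    # low-quality cells: binomially downsample total UMIs below 600
    lowq_idx = np.flatnonzero(is_lowq)
    totals = counts.sum(axis=1)
    for i in lowq_idx:
        if totals[i] == 0:
            continue
        target = rng.integers(50, min(550, max(51, totals[i])))
        keep_p = min(1.0, target / totals[i])
        counts[i] = rng.binomial(counts[i], keep_p)

    cluster_label = clusters.copy()
    cluster_label[is_doublet] = -1
    truth = pd.DataFrame(
        {
            "cluster": cluster_label,
            "is_doublet": is_doublet,
            "is_low_quality": is_lowq,
            "class_label": np.where(
                is_doublet, "doublet", np.char.add("class_", clusters.astype(str))
            ),
        }
    )
    truth.attrs["marker_genes"] = marker_genes
    truth.attrs["shared_genes"] = shared_genes
    truth.attrs["profiles"] = profiles

    m = ExpressionMatrix(
        counts=counts,
        cell_attrs=pd.DataFrame(
            {
                "CellID": [f"cell_{i}" for i in range(d.n_cells)],
                "Tissue": "synthetic",
                "SampleID": "sample_0",
                "TrueCluster": cluster_label,
            }
        ),
    )
    return m, truth


# ---------------------------------------------------------------------------
# Voxel atlas
# ---------------------------------------------------------------------------


@dataclass
class VoxelAtlas:
    """Per-gene expression energy on a 3-D voxel grid.

    ``energy`` is genes × voxels over the flattened grid; voxels outside the
    valid anatomical domain carry energy −1 for every gene.  ``region_labels``
    assigns each valid voxel an anatomical region id (−1 outside the domain).
    """

    energy: np.ndarray
    gene_symbols: np.ndarray
    shape: tuple
    region_labels: np.ndarray
    voxel_size_um: float = 200.0

    def __post_init__(self):
        self.energy = np.asarray(self.energy, dtype=float)
        self.region_labels = np.asarray(self.region_labels).ravel()
        self.gene_symbols = np.asarray(self.gene_symbols)
        n_vox = int(np.prod(self.shape))
        if self.energy.shape != (len(self.gene_symbols), n_vox):
            raise ValueError("energy shape does not match genes × voxels")
        if self.region_labels.shape != (n_vox,):
            raise ValueError("region label grid does not match the voxel grid")
        valid = self.region_labels >= 0
        if (self.energy[:, ~valid] != -1).any():
            raise ValueError("invalid voxels must carry energy −1")
        if (self.energy[:, valid] < 0).any():
            raise ValueError("valid voxels must carry non-negative energy")

    @property
    def valid(self) -> np.ndarray:
        return self.region_labels >= 0


def slab_regions(shape: tuple, n_regions: int, invalid_margin: int = 1) -> np.ndarray:
    """Partition a 3-D grid into ``n_regions`` slabs along axis 0.

    A margin of voxels on every face is placed outside the valid domain
    (label −1), mimicking the empty space around a specimen.
    """
    labels = np.full(shape, -1, dtype=int)
    core = labels[
        invalid_margin : shape[0] - invalid_margin,
        invalid_margin : shape[1] - invalid_margin,
        invalid_margin : shape[2] - invalid_margin,
    ]
    edges = np.linspace(0, core.shape[0], n_regions + 1).astype(int)
    for r in range(n_regions):
        core[edges[r] : edges[r + 1]] = r
    return labels


def generate_voxel_atlas(
    shape: tuple,
    regions: np.ndarray,
    region_genes: dict[str, int],
    noise_sd: float = 0.3,
    seed: int = 0,
    base_energy: float = 0.5,
    high_energy: float = 8.0,
    n_background_genes: int = 15,
):
    """Build a synthetic voxel atlas plus the matched cluster profile.

    Each gene in ``region_genes`` has energy ``high_energy`` inside its region
    and ``base_energy`` elsewhere, plus truncated Gaussian noise;
    ``n_background_genes`` extra genes are uniform across the valid domain.
    The returned :class:`ClusterProfile` holds one cluster per region whose
    expression mirrors that region's gene program, so the spatial mapping
    stage can be scored against the planted regions.
    """
    regions = np.asarray(regions)
    if regions.shape != tuple(shape):
        raise DesignError("region label array does not match the grid shape")
    rng = np.random.default_rng(seed)
    labels_flat = regions.ravel()
    valid = labels_flat >= 0
    region_ids = np.unique(labels_flat[valid])
    for gene, rid in region_genes.items():
        if rid not in region_ids:
            raise DesignError(f"gene {gene!r} references unknown region {rid}")

    genes = list(region_genes) + [f"Bg{i:03d}" for i in range(n_background_genes)]
    n_vox = labels_flat.size
    energy = np.full((len(genes), n_vox), -1.0)
    for gi, gene in enumerate(genes):
        base = np.full(valid.sum(), base_energy)
        if gene in region_genes:
            base[labels_flat[valid] == region_genes[gene]] = high_energy
        else:
            # background genes vary smoothly so they carry no regional signal
            base *= rng.uniform(2.0, 8.0)
        if noise_sd > 0:
            base = np.clip(base + rng.normal(0, noise_sd, base.shape), 0, None)
        energy[gi, valid] = base

    atlas = VoxelAtlas(
        energy=energy,
        gene_symbols=np.array(genes),
        shape=tuple(shape),
        region_labels=labels_flat,
    )

    # matched profile: one cluster per region, expressing that region's genes
    n_clusters = len(region_ids)
    mean_expr = np.full((n_clusters, len(genes)), base_energy)
    for gi, gene in enumerate(genes):
        if gene in region_genes:
            ci = int(np.searchsorted(region_ids, region_genes[gene]))
            mean_expr[ci, gi] = high_energy
        else:
            mean_expr[:, gi] = rng.uniform(2.0, 8.0)
    profile = ClusterProfile(
        mean_expr=mean_expr,
        nonzero_frac=np.clip(mean_expr / (1.0 + mean_expr), 0, 1),
        cell_counts=np.full(n_clusters, 100),
        gene_symbols=np.array(genes),
        cluster_ids=region_ids,
    )
    return atlas, profile
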