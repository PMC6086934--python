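"""Voxel-atlas spatial mapping of cluster expression profiles.

Cluster profiles are correlated against a coarse 3-D grid of per-gene
in-situ expression "energy".  Genes are first filtered to the atlas's
high-quality set (mean energy > 0.2 over the valid domain and more than 30
voxels above energy 5), then both the atlas and the cluster profiles are
log2(x+1) transformed and z-normalized per gene; Pearson correlation over
the intersected gene set yields a cluster × voxel map.  Regional fold
enrichment tallies the anatomical regions of each cluster's 100 strongest
voxels against the regions' overall frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import zoom

from .data_model import ClusterProfile
from .synthetic import VoxelAtlas

__all__ = ["SpatialParams", "map_types_to_voxels", "region_fold_enrichment"]


@dataclass
class SpatialParams:
    min_mean_energy: float = 0.2
    min_high_voxels: int = 30
    high_energy_threshold: float = 5.0
    top_voxels_for_enrichment: int = 100
    interpolate: bool = False
    upsample_factor: int = 2

    def __post_init__(self):
        if min(self.min_mean_energy, self.min_high_voxels) <= 0:
            raise ValueError("thresholds must be positive")


def _quality_filter(atlas: VoxelAtlas, p: SpatialParams) -> np.ndarray:
    valid = atlas.valid
    e = atlas.energy[:, valid]
    mean_ok = e.mean(axis=1) > p.min_mean_energy
    high_ok = (e > p.high_energy_threshold).sum(axis=1) > p.min_high_voxels
    return mean_ok & high_ok


def _z_normalize_atlas(atlas: VoxelAtlas, gene_idx: np.ndarray) -> np.ndarray:
    """log2(e+1), centered/scaled per gene; moments over positive voxels."""
    valid = atlas.valid
    out = np.zeros((len(gene_idx), int(valid.sum())))
    for row, gi in enumerate(gene_idx):
        e = atlas.energy[gi, valid]
        pos = e > 0
        logs = np.log2(e + 1.0)
        ref = logs[pos] if pos.any() else logs
        m, s = ref.mean(), ref.std()
        out[row] = (logs - m) / (s if s > 0 else 1.0)
    return out


def map_types_to_voxels(
    profile: ClusterProfile,
    atlas: VoxelAtlas,
    genes: np.ndarray = None,
    p: SpatialParams = None,
):
    """Correlate each cluster with each valid voxel.

    ``genes`` optionally restricts the comparison to a pre-selected gene
    list (e.g. the taxonomy's linkage genes); it is intersected with the
    atlas's high-quality gene set.  Returns ``(corr, used_genes)`` where
    ``corr`` has shape (clusters,) + grid shape, with NaN outside the valid
    domain.
    """
    p = p or SpatialParams()
    quality = _quality_filter(atlas, p)
    atlas_genes = {s: i for i, s in enumerate(atlas.gene_symbols)}
    profile_genes = {s: i for i, s in enumerate(profile.gene_symbols)}
    wanted = set(map(str, genes)) if genes is not None else set(profile_genes)

    pairs = []  # (profile idx, atlas idx)
    n_named = n_in_atlas = 0
    for sym in sorted(wanted):
        if sym not in profile_genes:
            continue
        n_named += 1
        ai = atlas_genes.get(sym)
        if ai is None:
            continue
        n_in_atlas += 1
        if quality[ai]:
            pairs.append((profile_genes[sym], ai))
    if len(pairs) < 10:
        raise ValueError(
            f"only {len(pairs)} usable genes (named: {n_named}, in atlas: "
            f"{n_in_atlas}, passing quality: {len(pairs)}); need >= 10"
        )
    prof_idx = np.array([a for a, _ in pairs])
    atlas_idx = np.array([b for _, b in pairs])

    vox = _z_normalize_atlas(atlas, atlas_idx)  # genes × valid voxels
    logp = np.log2(np.asarray(profile.mean_expr, dtype=float)[:, prof_idx] + 1.0)
    m = logp.mean(axis=0)
    s = logp.std(axis=0)
    s[s == 0] = 1.0
    prof = (logp - m) / s  # clusters × genes

    # Pearson correlation over the gene axis
    pc = prof - prof.mean(axis=1, keepdims=True)
    vc = vox - vox.mean(axis=0, keepdims=True)
    pn = np.linalg.norm(pc, axis=1)
    vn = np.linalg.norm(vc, axis=0)
    pn[pn == 0] = 1.0
    vn[vn == 0] = 1.0
    corr_valid = (pc @ vc) / pn[:, None] / vn[None, :]

    n_vox = int(np.prod(atlas.shape))
    corr = np.full((profile.n_clusters, n_vox), np.nan)
    corr[:, atlas.valid] = corr_valid
    corr = corr.reshape((profile.n_clusters,) + tuple(atlas.shape))
    if p.interpolate:
        f = p.upsample_factor
        corr = np.stack(
            [zoom(np.nan_to_num(c, nan=-1.0), f, order=1) for c in corr]
        )
    used = [str(profile.gene_symbols[i]) for i in prof_idx]
    return corr, used


def region_fold_enrichment(
    corr: np.ndarray, atlas: VoxelAtlas, p: SpatialParams = None
) -> pd.DataFrame:
    """Fold enrichment of anatomical regions among each cluster's top voxels.

    For each cluster the ``top_voxels_for_enrichment`` highest-correlation
    valid voxels (stable tie-break by voxel index) are tallied by region;
    fold = frequency among top voxels / frequency among all valid voxels.
    Regions absent from the top set get fold 0.  Returns a tidy frame
    (cluster, region, fold) sorted by fold within cluster.
    """
    p = p or SpatialParams()
    n_clusters = corr.shape[0]
    flat = corr.reshape(n_clusters, -1)
    valid_idx = np.flatnonzero(atlas.valid)
    labels = atlas.region_labels[valid_idx]
    regions, overall = np.unique(labels, return_counts=True)
    overall_freq = overall / overall.sum()

    n_top = p.top_voxels_for_enrichment
    if len(valid_idx) < n_top:
        warnings.warn(
            f"only {len(valid_idx)} valid voxels; using all for enrichment"
        )
        n_top = len(valid_idx)

    rows = []
    for ci in range(n_clusters):
        vals = flat[ci, valid_idx]
        order = np.lexsort((valid_idx, -vals))[:n_top]
        top_labels = labels[order]
        for ri, region in enumerate(regions):
            freq = np.mean(top_labels == region)
            rows.append(
                {
                    "cluster": ci,
                    "region": int(region),
                    "fold": float(freq / overall_freq[ri]),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["cluster", "fold"], ascending=[True, False]).reset_index(
        drop=True
    )
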