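import numpy as np
import pytest

import cellgraph as cg
from cellgraph.spatial import SpatialParams
from cellgraph.synthetic import slab_regions


@pytest.fixture(scope="module")
def atlas_and_profile():
    shape = (14, 10, 10)
    regions = slab_regions(shape, 5)
    region_genes = {f"Reg{r}_{i}": r for r in range(5) for i in range(5)}
    return cg.generate_voxel_atlas(
        shape, regions, region_genes, noise_sd=0.4, seed=17
    )


class TestMapTypesToVoxels:
    def test_region_clusters_peak_in_their_region(self, atlas_and_profile):
        atlas, profile = atlas_and_profile
        corr, used = cg.map_types_to_voxels(profile, atlas)
        flat = corr.reshape(profile.n_clusters, -1)
        hits = 0
        for ci, region in enumerate(profile.cluster_ids):
            best = np.nanargmax(flat[ci])
            hits += atlas.region_labels[best] == region
        assert hits / profile.n_clusters >= 0.9

    def test_self_profile_voxel_correlates_exactly_one(self):
        """Feeding the cluster profiles themselves in as voxels makes both
        normalizations identical, so voxel i matches cluster i at 1."""
        rng = np.random.default_rng(23)
        n_clusters, n_genes = 12, 30
        mean_expr = rng.uniform(1.0, 10.0, size=(n_clusters, n_genes))
        profile = cg.ClusterProfile(
            mean_expr=mean_expr,
            nonzero_frac=np.clip(mean_expr / 10, 0, 1),
            cell_counts=np.full(n_clusters, 50),
            gene_symbols=np.array([f"G{i}" for i in range(n_genes)]),
        )
        atlas = cg.VoxelAtlas(
            energy=mean_expr.T,  # genes × voxels, one voxel per cluster
            gene_symbols=profile.gene_symbols.copy(),
            shape=(n_clusters, 1, 1),
            region_labels=np.arange(n_clusters),
        )
        p = SpatialParams(min_mean_energy=0.1, min_high_voxels=1)
        corr, used = cg.map_types_to_voxels(profile, atlas, p=p)
        flat = corr.reshape(n_clusters, -1)
        np.testing.assert_allclose(np.diag(flat), 1.0, atol=1e-12)

    def test_low_energy_gene_excluded(self):
        shape = (8, 8, 8)
        regions = slab_regions(shape, 2)
        region_genes = {f"R{r}_{i}": r for r in range(2) for i in range(8)}
        atlas, profile = cg.generate_voxel_atlas(
            shape, regions, region_genes, noise_sd=0.0, seed=1,
            base_energy=0.5, high_energy=8.0,
        )
        # force one gene to near-zero energy everywhere
        gi = list(atlas.gene_symbols).index("R0_0")
        atlas.energy[gi, atlas.valid] = 0.1
        corr, used = cg.map_types_to_voxels(profile, atlas)
        assert "R0_0" not in used

    def test_too_few_usable_genes_error_names_counts(self):
        shape = (6, 6, 6)
        regions = slab_regions(shape, 2)
        atlas, profile = cg.generate_voxel_atlas(
            shape, regions, {"A": 0, "B": 1}, noise_sd=0.0, seed=2,
            n_background_genes=2,
        )
        atlas.energy[:, atlas.valid] = 0.01  # fail the quality filter
        with pytest.raises(ValueError, match="usable genes"):
            cg.map_types_to_voxels(profile, atlas)

    def test_correlations_bounded_and_invalid_voxels_nan(self, atlas_and_profile):
        atlas, profile = atlas_and_profile
        corr, _ = cg.map_types_to_voxels(profile, atlas)
        flat = corr.reshape(profile.n_clusters, -1)
        assert np.nanmin(flat) >= -1.0 - 1e-12
        assert np.nanmax(flat) <= 1.0 + 1e-12
        assert np.isnan(flat[:, ~atlas.valid]).all()

    def test_invariant_to_per_gene_affine_rescaling(self, atlas_and_profile):
        """z-normalization cancels per-gene affine changes of the
        log-energies, so the correlation field is unchanged (exact on a
        strictly positive atlas, where the moment mask covers every valid
        voxel)."""
        _, profile = atlas_and_profile
        shape = (14, 10, 10)
        regions = slab_regions(shape, 5)
        region_genes = {f"Reg{r}_{i}": r for r in range(5) for i in range(5)}
        atlas, _ = cg.generate_voxel_atlas(
            shape, regions, region_genes, noise_sd=0.05, seed=17
        )
        assert (atlas.energy[:, atlas.valid] > 0).all()
        corr1, used = cg.map_types_to_voxels(profile, atlas)
        rng = np.random.default_rng(3)
        energy = atlas.energy.copy()
        valid = atlas.valid
        for gi in range(energy.shape[0]):
            a = rng.uniform(1.0, 1.2)
            b = rng.uniform(0.0, 0.3)
            # affine map of log2(e+1): e' = 2^(a*log2(e+1)+b) − 1 ≥ 0,
            # applied to positive voxels so the moment mask (energy > 0)
            # the normalization uses is preserved
            pos = valid & (energy[gi] > 0)
            logs = np.log2(energy[gi, pos] + 1.0)
            energy[gi, pos] = 2.0 ** (a * logs + b) - 1.0
        atlas2 = cg.VoxelAtlas(
            energy=energy,
            gene_symbols=atlas.gene_symbols.copy(),
            shape=atlas.shape,
            region_labels=atlas.region_labels.copy(),
        )
        corr2, used2 = cg.map_types_to_voxels(profile, atlas2, genes=used)
        assert used2 == used
        np.testing.assert_allclose(corr1, corr2, equal_nan=True, atol=1e-9)


class TestRegionFoldEnrichment:
    def test_fold_of_fully_occupying_ten_percent_region(self):
        """Top-100 voxels all inside a region occupying 10% of the valid
        domain → fold exactly 10."""
        shape = (12, 10, 10)
        labels = np.full(shape, 1, dtype=int)
        labels[:1, :5] = 0  # 50 of 1200... adjust to exactly 10%
        labels = np.full(shape, 1, dtype=int)
        flat = labels.ravel()
        flat[:120] = 0  # region 0 occupies exactly 10% of 1200 voxels
        atlas = cg.VoxelAtlas(
            energy=np.zeros((1, 1200)),
            gene_symbols=np.array(["G"]),
            shape=shape,
            region_labels=flat,
        )
        corr = np.zeros((1, 1200))
        corr[0, :120] = 0.9  # top voxels exactly fill region 0
        corr = corr.reshape((1,) + shape)
        table = cg.region_fold_enrichment(corr, atlas)
        fold0 = table.query("region == 0")["fold"].iloc[0]
        fold1 = table.query("region == 1")["fold"].iloc[0]
        assert fold0 == pytest.approx(10.0)
        assert fold1 == pytest.approx(0.0)

    def test_constant_correlations_give_unit_folds_by_tiebreak(self):
        shape = (10, 10, 10)
        flat = np.repeat(np.arange(10), 100)  # 10 equal regions in order
        atlas = cg.VoxelAtlas(
            energy=np.zeros((1, 1000)),
            gene_symbols=np.array(["G"]),
            shape=shape,
            region_labels=flat,
        )
        corr = np.zeros((1,) + shape)
        table = cg.region_fold_enrichment(corr, atlas)
        # deterministic tie-break takes the first 100 voxels = region 0
        assert table.query("region == 0")["fold"].iloc[0] == pytest.approx(10.0)

    def test_fewer_valid_voxels_than_top_k_warns(self):
        shape = (3, 3, 3)
        flat = np.zeros(27, dtype=int)
        atlas = cg.VoxelAtlas(
            energy=np.zeros((1, 27)),
            gene_symbols=np.array(["G"]),
            shape=shape,
            region_labels=flat,
        )
        corr = np.zeros((1,) + shape)
        with pytest.warns(UserWarning, match="valid voxels"):
            table = cg.region_fold_enrichment(corr, atlas)
        assert table["fold"].iloc[0] == pytest.approx(1.0)
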