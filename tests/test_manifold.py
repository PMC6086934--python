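import numpy as np
import pytest
import scipy.sparse as sp

import cellgraph as cg
from cellgraph.manifold import ManifoldParams


class TestSelectInformativeGenes:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(200, 50))
        counts[:, 7] = 3  # constant gene: CV = 0
        m = cg.ExpressionMatrix(counts=counts)
        genes = cg.select_informative_genes(m, ManifoldParams(n_genes=49))
        assert 7 not in genes

    def test_overdispersed_gene_ranks_in_top_set(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(400, 100))
        # planted overdispersed gene: same mean, far larger variance
        burst = rng.random(400) < 0.1
        counts[:, 42] = np.where(burst, rng.poisson(20, 400), 0)
        m = cg.ExpressionMatrix(counts=counts)
        genes = cg.select_informative_genes(m, ManifoldParams(n_genes=10))
        assert 42 in genes

    def test_clipped_when_few_valid_genes(self):
        rng = np.random.default_rng(2)
        m = cg.ExpressionMatrix(counts=rng.poisson(1.5, size=(100, 30)))
        genes = cg.select_informative_genes(m, ManifoldParams(n_genes=1000))
        assert len(genes) <= 30

    def test_excluded_symbols_never_selected(self):
        rng = np.random.default_rng(3)
        import pandas as pd

        counts = rng.poisson(2.0, size=(100, 20))
        attrs = pd.DataFrame({"Gene": [f"G{i}" for i in range(19)] + ["Xist"]})
        counts[:, 19] = rng.poisson(rng.gamma(1, 5, 100))  # very variable
        m = cg.ExpressionMatrix(counts=counts, gene_attrs=attrs)
        genes = cg.select_informative_genes(m, ManifoldParams(n_genes=20))
        assert 19 not in genes

    def test_second_pass_returns_enriched_markers(self, small_sim):
        _, m, truth = small_sim
        cg.filter_valid(m)
        labels = truth["cluster"].to_numpy()
        genes = cg.select_informative_genes(
            m, ManifoldParams(genes_per_cluster=10), cluster_labels=labels
        )
        marker_sets = truth.attrs["marker_genes"]
        planted = set(np.concatenate(list(marker_sets.values())).tolist())
        assert len(planted & set(genes.tolist())) >= 0.7 * len(planted)


class TestNormalizeCells:
    def test_per_gene_means_are_zero(self, small_sim):
        _, m, _ = small_sim
        cg.filter_valid(m)
        genes = np.flatnonzero(m.gene_valid)[:100]
        x = cg.normalize_cells(m, genes)
        np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=1e-9)

    def test_scaling_to_common_total(self):
        """A cell with raw total 10,000 is halved before the log transform:
        undoing the per-gene centering recovers log2(raw/2 + 1)."""
        counts = np.zeros((2, 4), dtype=int)
        counts[0] = [2500, 2500, 2500, 2500]  # total 10,000 → scale 1/2
        counts[1] = [1250, 1250, 1250, 1250]  # total 5,000 → scale 1
        m = cg.ExpressionMatrix(counts=counts)
        x = cg.normalize_cells(m, np.arange(4))
        # both cells normalize to the same vector, so centering maps both
        # rows to zero; the pre-centering values are log2(1251)
        np.testing.assert_allclose(x, 0.0, atol=1e-12)
        gene_means = np.log2(counts[1] + 1.0)  # the centering offset
        np.testing.assert_allclose(
            x[0] + gene_means, np.log2(2500 * 0.5 + 1.0), atol=1e-12
        )

    def test_zero_total_cell_is_error(self):
        counts = np.array([[1, 2], [0, 0]])
        m = cg.ExpressionMatrix(counts=counts)
        with pytest.raises(ValueError, match="zero total"):
            cg.normalize_cells(m, np.arange(2))


class TestSignificantComponents:
    def test_pure_noise_retains_nothing_or_flags_fallback(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 80))
        x -= x.mean(axis=0)
        y, info = cg.significant_components(x, seed=0)
        assert info["fallback"] and info["n_retained"] == 1

    def test_planted_factor_recovered(self):
        rng = np.random.default_rng(5)
        factor = rng.normal(size=300)
        loadings = rng.normal(size=60)
        x = np.outer(factor, loadings) * 2.0 + rng.normal(size=(300, 60))
        x -= x.mean(axis=0)
        y, info = cg.significant_components(x, seed=0)
        assert info["n_retained"] >= 1
        r = np.corrcoef(y[:, 0], factor)[0, 1]
        assert abs(r) > 0.9

    def test_rank_bound(self, small_sim):
        _, m, _ = small_sim
        cg.filter_valid(m)
        genes = np.flatnonzero(m.gene_valid)[:50]
        x = cg.normalize_cells(m, genes)
        y, info = cg.significant_components(x, seed=0)
        assert info["n_retained"] <= min(x.shape) - 1


class TestBalancedKnn:
    def test_weights_follow_inverse_rank(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(50, 3))
        p = ManifoldParams(k=8, max_incoming=200)
        g = cg.build_multiscale_knn(y, p)
        row = g.knn.getrow(0)
        expected = {1.0 / r for r in range(1, 9)}
        assert set(np.round(row.data, 12)) <= {round(1.0 / r, 12) for r in range(1, 9)}
        assert np.isclose(row.data.max(), 1.0)

    def test_mutual_graph_equals_bruteforce_reciprocation(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(120, 4))
        p = ManifoldParams(k=10, max_incoming=200)
        g = cg.build_multiscale_knn(y, p)
        # brute-force: full pairwise distances, k nearest per cell
        d = ((y[:, None, :] - y[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        nbrs = np.argsort(d, axis=1)[:, :10]
        directed = {(i, j) for i in range(120) for j in nbrs[i]}
        mutual = {(i, j) for (i, j) in directed if (j, i) in directed}
        got = set(zip(*g.mknn.nonzero()))
        assert got == mutual

    def test_incoming_edge_cap(self):
        # 251 satellites on orthogonal axes all propose the hub at rank 1
        n_sat = 251
        y = np.zeros((n_sat + 1, n_sat))
        for i in range(n_sat):
            y[i + 1, i] = 1e6
        p = ManifoldParams(k=1, max_incoming=200)
        g = cg.build_multiscale_knn(y, p)
        incoming = np.asarray((g.knn > 0).sum(axis=0)).ravel()
        assert incoming[0] == 200

    def test_no_self_edges_and_weight_range(self):
        rng = np.random.default_rng(8)
        g = cg.build_multiscale_knn(rng.normal(size=(60, 2)), ManifoldParams(k=5))
        assert g.knn.diagonal().sum() == 0
        assert g.knn.data.min() > 0 and g.knn.data.max() <= 1.0

    def test_k_too_large_is_error(self):
        with pytest.raises(ValueError, match="smaller"):
            cg.build_multiscale_knn(np.zeros((5, 2)), ManifoldParams(k=5))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(80, 3))
        p = ManifoldParams(k=6)
        g = cg.build_multiscale_knn(y, p)
        perm = rng.permutation(80)
        gp = cg.build_multiscale_knn(y[perm], p)
        pmat = sp.csr_matrix(
            (np.ones(80), (np.arange(80), np.argsort(perm))), shape=(80, 80)
        )
        # permuting rows of the input permutes the graph identically
        assert ((pmat.T @ g.knn @ pmat) != gp.knn).nnz == 0


class TestGtsne:
    def test_output_shape_and_determinism(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(100, 3))
        g = cg.build_multiscale_knn(y, ManifoldParams(k=10))
        e1 = cg.embed_gtsne(g, seed=3, n_iter=120)
        g2 = cg.build_multiscale_knn(y, ManifoldParams(k=10))
        e2 = cg.embed_gtsne(g2, seed=3, n_iter=120)
        assert e1.shape == (100, 2)
        np.testing.assert_array_equal(e1, e2)

    def test_identical_weight_profiles_embed_together(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(80, 3)) * 5
        y = np.vstack([base, base[:1]])  # cell 80 duplicates cell 0
        g = cg.build_multiscale_knn(y, ManifoldParams(k=10))
        # force identical outgoing weight profiles for the pair, keeping a
        # mutual rank-1 edge between them
        knn = g.knn.tolil()
        knn[80, :] = knn[0, :]
        knn[80, 80] = 0.0
        knn[80, 0] = knn[0, 80]
        g.knn = knn.tocsr()
        emb = cg.embed_gtsne(g, seed=0, n_iter=250)
        d_pair = np.linalg.norm(emb[0] - emb[80])
        from scipy.spatial.distance import pdist

        assert d_pair < np.percentile(pdist(emb), 1)

    def test_cluster_purity_in_embedding(self, small_sim):
        _, m, truth = small_sim
        cg.filter_valid(m)
        mv = m.subset_cells(m.cell_valid)
        tv = truth[m.cell_valid].reset_index(drop=True)
        p = ManifoldParams(n_genes=500, k=50)
        genes = cg.select_informative_genes(mv, p)
        x = cg.normalize_cells(mv, genes, p)
        y, _ = cg.significant_components(x, p, seed=0)
        g = cg.build_multiscale_knn(y, p)
        emb = cg.embed_gtsne(g, seed=0)
        genuine = (~tv["is_doublet"]).to_numpy()
        labels = tv["cluster"].to_numpy()
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=11).fit(emb[genuine])
        _, idx = nn.kneighbors(emb[genuine])
        lab = labels[genuine]
        purity = np.mean(
            [np.mean(lab[idx[i, 1:]] == lab[i]) for i in range(len(lab))]
        )
        assert purity > 0.9
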