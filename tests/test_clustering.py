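import numpy as np
import pytest
import scipy.sparse as sp

import cellgraph as cg
from cellgraph.clustering import ClusterParams, ClusterResult, _louvain, _renumber
from cellgraph.manifold import CellGraph, ManifoldParams


def _graph_from_points(points, k=10):
    g = cg.build_multiscale_knn(points, ManifoldParams(k=k))
    return g


def _blobs(n_per=250, sep=20.0, seed=5, dim=6, n_blobs=4):
    # blobs live in a PC-like space of moderate dimension, where KNN graphs
    # of Gaussian clusters are expander-like rather than lattice-like.
    # Several blobs are used so each community is a small fraction of the
    # graph's edges: modularity clustering protects communities in that
    # regime but deliberately re-partitions a community holding half or
    # more of all edges.
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_blobs, dim))
    for i in range(n_blobs):
        centers[i, i % dim] = sep * (1 + i // dim)
    pts = np.vstack([rng.normal(size=(n_per, dim)) + c for c in centers])
    labels = np.repeat(np.arange(n_blobs), n_per)
    return pts, labels


class TestPolishedLouvain:
    def test_separated_blobs_fully_recovered_without_splits(self):
        pts, truth = _blobs()
        g = _graph_from_points(pts, k=100)
        cg.embed_gtsne(g, seed=0, n_iter=250)
        res = cg.polished_louvain(g, ClusterParams(seed=0))
        from sklearn.metrics import adjusted_rand_score

        assert res.n_clusters == 4
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_tiny_satellite_group_becomes_outliers(self):
        rng = np.random.default_rng(1)
        main = rng.normal(size=(400, 6))
        satellite = rng.normal(size=(8, 6)) * 0.1 + 60.0
        pts = np.vstack([main, satellite])
        g = _graph_from_points(pts, k=30)
        cg.embed_gtsne(g, seed=0, n_iter=200)
        res = cg.polished_louvain(g, ClusterParams(seed=0))
        assert (res.labels[400:] == cg.OUTLIER_LABEL).all()

    def test_polishing_never_merges_louvain_communities(self):
        """Every polished cluster descends from exactly one Louvain
        community: polishing relabels to outlier or splits, never merges."""
        pts, _ = _blobs(n_per=200, seed=6)
        g = _graph_from_points(pts, k=60)
        cg.embed_gtsne(g, seed=0, n_iter=200)
        base = _renumber(_louvain(g.mknn, 1.0, 0))
        res = cg.polished_louvain(g, ClusterParams(seed=0))
        for c in range(res.n_clusters):
            members = res.labels == c
            # allow smoothing to flip a few boundary cells
            top = np.bincount(base[members]).max()
            assert top >= 0.95 * members.sum()

    def test_missing_embedding_is_error(self):
        rng = np.random.default_rng(3)
        g = cg.build_multiscale_knn(rng.normal(size=(50, 2)), ManifoldParams(k=5))
        with pytest.raises(ValueError, match="embed_gtsne"):
            cg.polished_louvain(g, ClusterParams())

    def test_determinism(self):
        pts, _ = _blobs(n_per=150, seed=4)
        g = _graph_from_points(pts, k=20)
        cg.embed_gtsne(g, seed=1, n_iter=150)
        r1 = cg.polished_louvain(g, ClusterParams(seed=5))
        r2 = cg.polished_louvain(g, ClusterParams(seed=5))
        np.testing.assert_array_equal(r1.labels, r2.labels)


class TestLouvainOracle:
    def _all_partitions(self, n, max_blocks):
        def rec(i, blocks):
            if i == n:
                yield [list(b) for b in blocks]
                return
            for b in blocks:
                b.append(i)
                yield from rec(i + 1, blocks)
                b.pop()
            if len(blocks) < max_blocks:
                blocks.append([i])
                yield from rec(i + 1, blocks)
                blocks.pop()

        yield from rec(0, [])

    def test_louvain_attains_exhaustive_modularity_optimum(self):
        """On a 10-node two-clique graph, the returned partition's
        modularity equals the exhaustive optimum over <= 4 communities."""
        import igraph

        n = 10
        adj = np.zeros((n, n))
        for grp in (range(5), range(5, 10)):
            for i in grp:
                for j in grp:
                    if i != j:
                        adj[i, j] = 1.0
        adj[4, 5] = adj[5, 4] = 0.5  # weak bridge
        mknn = sp.csr_matrix(adj)
        membership = _louvain(mknn, resolution=1.0, seed=0)

        coo = sp.triu(mknn, k=1).tocoo()
        g = igraph.Graph(
            n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        got = g.modularity(membership.tolist(), weights="weight")
        best = max(
            g.modularity(
                [next(bi for bi, b in enumerate(part) if v in b) for v in range(n)],
                weights="weight",
            )
            for part in self._all_partitions(n, 4)
        )
        assert got >= best - 1e-9


class TestSmoothLabels:
    def _chain_graph(self, labels_of_neighbors):
        """Star: cell 0 with 10 neighbours carrying given labels."""
        n = 11
        w = sp.lil_matrix((n, n))
        for r, j in enumerate(range(1, 11)):
            w[0, j] = 1.0 / (r + 1)
        for j in range(1, 11):
            w[j, 0] = 1.0
        g = CellGraph.__new__(CellGraph)
        g.knn = w.tocsr()
        g.mknn = sp.csr_matrix((n, n))
        g.embedding = np.zeros((n, 2))
        return g

    def test_unanimous_neighbors(self):
        g = self._chain_graph(None)
        labels = np.array([3] + [7] * 10)
        out = cg.smooth_labels(labels, g, k=10)
        assert out[0] == 7

    def test_majority_wins(self):
        g = self._chain_graph(None)
        labels = np.array([9] + [0] * 6 + [1] * 4)
        assert cg.smooth_labels(labels, g, k=10)[0] == 0

    def test_tie_goes_to_lower_label(self):
        g = self._chain_graph(None)
        labels = np.array([9] + [2] * 5 + [1] * 5)
        assert cg.smooth_labels(labels, g, k=10)[0] == 1

    def test_fewer_neighbors_than_k_warns_and_uses_all(self):
        g = self._chain_graph(None)
        labels = np.array([9] + [4] * 10)
        with pytest.warns(UserWarning, match="neighbours"):
            out = cg.smooth_labels(labels, g, k=50)
        assert out[0] == 4


class TestRenumber:
    def test_decreasing_size_order(self):
        labels = np.array([5, 5, 5, 2, 2, 9, -1])
        out = _renumber(labels)
        assert out.tolist() == [0, 0, 0, 1, 1, 2, -1]


class TestAssessRobustness:
    def test_separable_clusters_near_perfect(self, small_sim):
        _, m, truth = small_sim
        genuine = ~truth["is_doublet"].to_numpy()
        mv = m.subset_cells(genuine)
        labels = truth.loc[genuine, "cluster"].to_numpy()
        res = ClusterResult(labels=labels)
        prob, report = cg.assess_robustness(mv, res, seed=0)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-9)
        assert np.diag(prob.to_numpy()).min() > 0.6
        assert np.diag(prob.to_numpy()).mean() > 0.7
        assert report["precision"].min() > 0.9
        assert report["recall"].min() > 0.9

    def test_duplicated_cluster_confuses_the_pair(self, small_sim):
        """Splitting one true cluster in two at random produces a pair the
        classifier cannot separate: their off-diagonal block matches the
        diagonal."""
        _, m, truth = small_sim
        rng = np.random.default_rng(0)
        genuine = ~truth["is_doublet"].to_numpy()
        mv = m.subset_cells(genuine)
        labels = truth.loc[genuine, "cluster"].to_numpy().copy()
        zero = labels == 0
        labels[zero & (rng.random(len(labels)) < 0.5)] = labels.max() + 1
        prob, _ = cg.assess_robustness(mv, ClusterResult(labels=labels), seed=0)
        pm = prob.to_numpy()
        pair = pm[np.ix_([0, labels.max()], [0, labels.max()])]
        assert abs(pair[0, 1] - pair[0, 0]) < 0.25
        assert abs(pair[1, 0] - pair[1, 1]) < 0.25

    def test_single_cluster_is_error(self, small_sim):
        _, m, _ = small_sim
        with pytest.raises(ValueError, match="two clusters"):
            cg.assess_robustness(m, ClusterResult(labels=np.zeros(m.n_cells, int)))
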