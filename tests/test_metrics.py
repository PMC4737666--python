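import numpy as np
import pytest
from hypothesis import given, strategies as st

from conngeo.embedding import Embedding
from conngeo.graph import all_pairs_shortest_paths, nodal_path_length, to_edge_lengths
from conngeo.io import NodeTable, WeightedConnectome
from conngeo.metrics import (
    betweenness_centrality,
    centrality_validation,
    clustering_coefficient,
    dimension_sweep,
    embeddedness_score,
    nodal_strength,
    rank_by_center_distance,
)
from conftest import random_connected_connectome
from _oracles import enumerate_betweenness


class TestStrength:
    def test_chain_row_sums(self, chain_connectome):
        assert nodal_strength(chain_connectome) == pytest.approx([1.0, 5.0, 4.0])

    @given(seed=st.integers(0, 10_000))
    def test_handshake_identity(self, seed):
        c = random_connected_connectome(np.random.default_rng(seed), 15)
        s = nodal_strength(c)
        assert s.sum() == pytest.approx(c.weights.sum())
        assert np.abs(s - c.weights.sum(axis=1)).max() < 1e-12


class TestClustering:
    def test_uniform_triangle_scores_one(self):
        w = (np.ones((3, 3)) - np.eye(3)) * 7.0
        assert clustering_coefficient(WeightedConnectome(w)) == pytest.approx([1, 1, 1])

    def test_star_has_no_triangles(self, star_connectome):
        assert clustering_coefficient(star_connectome) == pytest.approx([0, 0, 0, 0])

    def test_weighted_four_node_matches_triple_sum(self):
        rng = np.random.default_rng(3)
        w = np.zeros((4, 4))
        iu, ju = np.triu_indices(4, k=1)
        vals = rng.uniform(0.5, 5.0, iu.size)
        vals[1] = 0.0  # drop one edge so degrees differ
        w[iu, ju] = w[ju, iu] = vals
        c = WeightedConnectome(w)
        w_hat = np.cbrt(w / w.max())
        expected = np.zeros(4)
        for i in range(4):
            k = (w[i] > 0).sum()
            if k < 2:
                continue
            acc = sum(w_hat[i, j] * w_hat[i, h] * w_hat[j, h]
                      for j in range(4) for h in range(4)
                      if j != i and h != i and h != j)
            expected[i] = acc / (k * (k - 1))
        assert clustering_coefficient(c) == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_bounded_and_matches_networkx(self, seed):
        import networkx as nx

        c = random_connected_connectome(np.random.default_rng(seed), 10)
        ours = clustering_coefficient(c)
        assert np.all(ours >= 0) and np.all(ours <= 1)
        g = nx.from_numpy_array(c.weights)
        theirs = nx.clustering(g, weight="weight")
        assert ours == pytest.approx([theirs[i] for i in range(10)], abs=1e-12)


class TestBetweenness:
    def test_path_graph_interior_node(self):
        w = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        bc = betweenness_centrality(to_edge_lengths(WeightedConnectome(w)))
        assert bc == pytest.approx([0.0, 1.0, 0.0])

    def test_complete_graph_all_zero(self):
        w = np.ones((5, 5)) - np.eye(5)
        bc = betweenness_centrality(to_edge_lengths(WeightedConnectome(w)))
        assert bc == pytest.approx([0.0] * 5)

    @given(seed=st.integers(0, 2_000))
    def test_matches_path_enumeration(self, seed):
        c = random_connected_connectome(np.random.default_rng(seed), 7)
        g = to_edge_lengths(c)
        assert betweenness_centrality(g) == pytest.approx(
            enumerate_betweenness(g.lengths), abs=1e-9)

    @given(seed=st.integers(0, 2_000))
    def test_invariant_under_weight_scaling(self, seed):
        c = random_connected_connectome(np.random.default_rng(seed), 9)
        c2 = WeightedConnectome(c.weights * 5.0, c.labels)
        bc1 = betweenness_centrality(to_edge_lengths(c))
        bc2 = betweenness_centrality(to_edge_lengths(c2))
        assert bc1 == pytest.approx(bc2, abs=1e-9)


class TestEmbeddedness:
    def test_cycle_symmetry(self):
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 2.0
        c = WeightedConnectome(w)
        d = all_pairs_shortest_paths(to_edge_lengths(c))
        scores = embeddedness_score(c, d)
        assert np.ptp(scores) < 1e-9

    def test_star_hub_ranks_first(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = [3.0, 2.0, 1.5, 1.0]
        c = WeightedConnectome(w)
        d = all_pairs_shortest_paths(to_edge_lengths(c))
        scores = embeddedness_score(c, d)
        assert np.argsort(-scores, kind="stable")[0] == 0

    def test_user_ranking_passes_through(self, chain_connectome):
        d = all_pairs_shortest_paths(to_edge_lengths(chain_connectome))
        ranking = np.array([0.3, 0.1, 0.9])
        assert np.array_equal(embeddedness_score(chain_connectome, d, ranking), ranking)


class TestCentralityValidation:
    def test_perfectly_linear_relation(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(30, 3))
        dist = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
        npl = (dist - 0.5) / 2.0  # distance is exactly 2·npl + 0.5
        v = centrality_validation(coords, npl)
        assert v.r_squared == pytest.approx(1.0)
        assert v.slope == pytest.approx(2.0)
        assert v.intercept == pytest.approx(0.5)

    def test_random_coordinates_decorrelate(self, default_synthetic):
        c, _ = default_synthetic
        from conngeo.graph import all_pairs_shortest_paths, to_edge_lengths

        npl = nodal_path_length(all_pairs_shortest_paths(to_edge_lengths(c)))
        coords = np.random.default_rng(11).normal(size=(c.n, 3))
        assert centrality_validation(coords, npl).r_squared < 0.1

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(40, 3))
        npl = rng.uniform(1, 2, 40)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        v1 = centrality_validation(coords, npl)
        v2 = centrality_validation(coords @ q + 7.0, npl)
        assert v1.r_squared == pytest.approx(v2.r_squared, abs=1e-9)

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            centrality_validation(np.ones((5, 3)), np.arange(5.0))


class TestRanking:
    def _embedding(self, dists):
        coords = np.zeros((len(dists), 3))
        coords[:, 0] = dists
        coords -= coords.mean(axis=0)
        return Embedding(coords, "isomap", np.ones(3))

    def test_sorted_by_distance(self):
        # center distances (2, 1, 3): centroid is at the origin by construction
        e = Embedding(np.array([[2.0, 0, 0], [1.0, 0, 0], [-3.0, 0, 0]]),
                      "isomap", np.ones(3))
        t = NodeTable(("n0", "n1", "n2"))
        df = rank_by_center_distance(e, t)
        assert list(df["label"]) == ["n1", "n0", "n2"]
        assert list(df["rank"]) == [0, 1, 2]

    def test_equal_distances_break_by_label(self):
        e = Embedding(np.array([[1.0, 0, 0], [-1.0, 0, 0]]), "isomap", np.ones(3))
        df = rank_by_center_distance(e, NodeTable(("zeta", "alpha")))
        assert list(df["label"]) == ["alpha", "zeta"]


class TestDimensionSweep:
    def test_output_alignment_and_nonnegativity(self, default_synthetic):
        c, _ = default_synthetic
        from conngeo.model import IntrinsicGeometry

        m = IntrinsicGeometry(c)
        res = dimension_sweep(m.representation[:80, :80], m.nodal_path_length[:80],
                              dims=[1, 2, 3])
        assert res.dims == (1, 2, 3)
        assert len(res.rmse) == 3 and all(r >= 0 for r in res.rmse)
        assert all(k >= 3 for k in res.k_used)
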