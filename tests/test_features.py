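import networkx as nx
import numpy as np
import pytest

from xgbcda import (
    AssociationMatrix,
    SimilarityMatrix,
    ValidationError,
    assemble_pair_features,
    build_similarity_graph,
    centrality_features,
    nmf_latent,
    similarity_stats,
    topk_neighbor_stats,
)
from xgbcda.features import FeatureConfig, all_centralities, build_pair_features
from oracles import centralities_brute


def sim_of(M, ids=None):
    M = np.asarray(M, dtype=float)
    return SimilarityMatrix(ids or [f"x{i}" for i in range(M.shape[0])], M)


class TestSimilarityStats:
    def test_all_ones_row(self):
        sim = sim_of(np.ones((5, 5)))
        mean, hist = similarity_stats(sim, "x0", n_bins=10)
        assert mean == 1.0
        np.testing.assert_array_equal(hist, [0] * 9 + [4])

    def test_manual_binning(self):
        M = np.array([[1.0, 0.05, 0.15], [0.05, 1.0, 0.0], [0.15, 0.0, 1.0]])
        sim = sim_of(M)
        mean, hist = similarity_stats(sim, "x0", n_bins=10)
        assert mean == pytest.approx(0.10)
        np.testing.assert_array_equal(hist, [1, 1] + [0] * 8)

    def test_single_node_network(self):
        mean, hist = similarity_stats(sim_of([[1.0]]), "x0", n_bins=10)
        assert mean == 0.0
        np.testing.assert_array_equal(hist, np.zeros(10))

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            similarity_stats(sim_of(np.ones((2, 2))), "nope")


class TestSimilarityGraph:
    def test_uniform_matrix_has_no_edges(self):
        M = np.full((4, 4), 0.5)
        np.fill_diagonal(M, 1.0)
        g = build_similarity_graph(sim_of(M))
        assert g.number_of_edges() == 0

    def test_single_strong_pair(self):
        # off-diagonals {0.9, 0.1, 0.1}, mean ~0.3667 -> exactly one edge
        M = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        g = build_similarity_graph(sim_of(M))
        assert set(map(frozenset, g.edges)) == {frozenset({"x0", "x1"})}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        ids = [f"x{i}" for i in range(6)]
        g = build_similarity_graph(sim_of(M, ids))
        perm = rng.permutation(6)
        gp = build_similarity_graph(sim_of(M[np.ix_(perm, perm)], [ids[i] for i in perm]))
        assert set(map(frozenset, g.edges)) == set(map(frozenset, gp.edges))


class TestCentralities:
    def test_path_graph_center(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        nn, deg, clo, bet = centrality_features(g, "b")
        assert (nn, deg, clo, bet) == (2, 1.0, 1.0, 1.0)

    def test_complete_graph(self):
        g = nx.complete_graph(5)
        nn, deg, clo, bet = centrality_features(g, 0)
        assert deg == 1.0 and bet == 0.0

    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b")
        nn, deg, clo, bet = centrality_features(g, "c")
        assert (nn, deg, clo, bet) == (0, 0.0, 0.0, 0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, rng.random(), seed=int(rng.integers(2**31)))
            expected = centralities_brute(list(g.nodes), list(g.edges))
            got = all_centralities(g)
            for v in g.nodes:
                nn, deg, clo, bet = got[v]
                assert nn == expected[v]["n_neighbors"]
                assert deg == pytest.approx(expected[v]["degree"], abs=1e-9)
                assert clo == pytest.approx(expected[v]["closeness"], abs=1e-9)
                assert bet == pytest.approx(expected[v]["betweenness"], abs=1e-9)


class TestTopkNeighborStats:
    def test_sort_and_average(self):
        M = np.array(
            [[1.0, 0.9, 0.8, 0.1], [0.9, 1.0, 0.0, 0.0], [0.8, 0.0, 1.0, 0.0], [0.1, 0.0, 0.0, 1.0]]
        )
        mean, _ = topk_neighbor_stats(sim_of(M), "x0", k=2)
        assert mean == pytest.approx(0.85)

    def test_uniform_similarities(self):
        M = np.full((5, 5), 0.3)
        np.fill_diagonal(M, 1.0)
        mean, _ = topk_neighbor_stats(sim_of(M), "x0", k=3)
        assert mean == pytest.approx(0.3)

    def test_k_exceeding_n_reduces_to_all_neighbors(self):
        rng = np.random.default_rng(6)
        M = rng.random((5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        sim = sim_of(M)
        mean_all, _ = similarity_stats(sim, "x2")
        mean_topk, _ = topk_neighbor_stats(sim, "x2", k=99)
        assert mean_topk == pytest.approx(mean_all)


class TestNmf:
    def test_rank_one_matrix_recovered(self):
        u = np.array([1, 0, 1, 1, 0, 1])
        v = np.array([1, 1, 0, 1])
        A = np.outer(u, v)
        assoc = AssociationMatrix(
            [f"c{i}" for i in range(6)], [f"d{j}" for j in range(4)], A
        )
        lat = nmf_latent(assoc, rank=1, seed=0)
        recon = lat.circ_factors @ lat.disease_factors
        rel = np.linalg.norm(A - recon) / np.linalg.norm(A)
        assert rel < 1e-3
        assert (lat.circ_factors >= 0).all() and (lat.disease_factors >= 0).all()

    def test_zero_matrix_gives_zero_factors(self, toy_assoc):
        zero = AssociationMatrix(toy_assoc.circ_ids, toy_assoc.disease_ids, np.zeros((3, 2), dtype=int))
        lat = nmf_latent(zero, rank=2)
        assert not lat.circ_factors.any() and not lat.disease_factors.any()

    def test_seed_reproducibility(self, toy_assoc):
        a = nmf_latent(toy_assoc, rank=2, seed=3)
        b = nmf_latent(toy_assoc, rank=2, seed=3)
        np.testing.assert_array_equal(a.circ_factors, b.circ_factors)
        np.testing.assert_array_equal(a.disease_factors, b.disease_factors)

    def test_error_non_increasing_with_more_iterations(self, tiny_dataset):
        errs = []
        A = tiny_dataset.assoc.values.astype(float)
        for max_iter in (5, 20, 100):
            lat = nmf_latent(tiny_dataset.assoc, rank=3, seed=0, max_iter=max_iter, tol=0.0)
            errs.append(np.linalg.norm(A - lat.circ_factors @ lat.disease_factors))
        assert errs[0] >= errs[1] - 1e-9 >= errs[2] - 2e-9

    def test_rank_too_large_rejected(self, toy_assoc):
        with pytest.raises(ValidationError, match="rank"):
            nmf_latent(toy_assoc, rank=3)


class TestAssembly:
    @pytest.fixture()
    def parts(self, toy_assoc):
        rng = np.random.default_rng(8)
        M = rng.random((3, 3))
        cs = sim_of((M + M.T) / 2 * 0.5 + 0.25, toy_assoc.circ_ids)
        D = rng.random((2, 2))
        ds = sim_of((D + D.T) / 2 * 0.5 + 0.25, toy_assoc.disease_ids)
        lat = nmf_latent(toy_assoc, rank=2, seed=0)
        return cs, ds, lat

    def test_column_count_formula(self, parts):
        cs, ds, lat = parts
        n_bins = 7
        table = assemble_pair_features(cs, ds, lat, [("c1", "d1")], n_bins=n_bins)
        assert table.width == 2 * (2 * n_bins + 6) + 2 * lat.rank

    def test_identical_pairs_get_identical_rows(self, parts):
        cs, ds, lat = parts
        table = assemble_pair_features(cs, ds, lat, [("c1", "d2"), ("c1", "d2")])
        np.testing.assert_array_equal(table.values[0], table.values[1])

    def test_pair_order_swaps_rows_only(self, parts):
        cs, ds, lat = parts
        t1 = assemble_pair_features(cs, ds, lat, [("c1", "d1"), ("c2", "d2")])
        t2 = assemble_pair_features(cs, ds, lat, [("c2", "d2"), ("c1", "d1")])
        np.testing.assert_array_equal(t1.values[0], t2.values[1])
        np.testing.assert_array_equal(t1.values[1], t2.values[0])

    def test_unknown_id_raises(self, parts):
        cs, ds, lat = parts
        with pytest.raises(KeyError):
            assemble_pair_features(cs, ds, lat, [("ghost", "d1")])

    def test_end_to_end_builder_shapes(self, tiny_dataset):
        cfg = FeatureConfig(nmf_rank=4)
        pairs = tiny_dataset.assoc.positive_pairs()[:6]
        table = build_pair_features(
            tiny_dataset.assoc, tiny_dataset.expr, tiny_dataset.dsim, pairs, [1] * 6, cfg
        )
        assert table.values.shape == (6, 2 * (2 * cfg.n_bins + 6) + 2 * cfg.nmf_rank)
        assert np.isfinite(table.values).all()
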