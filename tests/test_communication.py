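"""Communication measures, their oracles, and structure-function coupling."""

import numpy as np
import pytest
from scipy.linalg import expm

from eventspan.communication import (
    CommunicationEnsemble,
    StructuralConnectome,
    communicability_binary,
    communicability_weighted,
    coupling_age_trend,
    coupling_matrix,
    euclidean_distance,
    extended_measures,
    max_r2_per_node,
    mean_first_passage_time,
    nodal_r2,
    normalize_sc,
    search_information,
)
from eventspan.nulls import spin_permutations


def _random_connected_sc(rng, n=12, density=0.4):
    while True:
        w = rng.random((n, n)) * (rng.random((n, n)) < density)
        w = np.triu(w, 1)
        w = w + w.T
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        if connected_components(csr_matrix(w), directed=False)[0] == 1:
            return w


class TestNormalizeSC:
    def test_geometric_volume_normalization(self):
        counts = np.array([[0.0, 10.0], [10.0, 0.0]])
        sc = normalize_sc(counts, np.array([4.0, 9.0]))
        assert sc.weights[0, 1] == pytest.approx(10.0 / 6.0)

    def test_equal_volumes_uniform_scaling(self, rng):
        counts = rng.random((5, 5))
        counts = counts + counts.T
        np.fill_diagonal(counts, 0.0)
        sc = normalize_sc(counts, np.full(5, 4.0))
        np.testing.assert_allclose(sc.weights, counts / 4.0)

    def test_matches_loop_oracle(self, rng):
        counts = rng.random((6, 6))
        counts = counts + counts.T
        np.fill_diagonal(counts, 0.0)
        vols = rng.uniform(1, 10, 6)
        sc = normalize_sc(counts, vols)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert sc.weights[i, j] == pytest.approx(
                        counts[i, j] / np.sqrt(vols[i] * vols[j])
                    )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            normalize_sc(np.zeros((2, 2)), np.array([1.0, 0.0]))


class TestEuclidean:
    def test_three_four_five(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert euclidean_distance(coords)[0, 1] == pytest.approx(5.0)

    def test_triangle_inequality_exhaustive(self, rng):
        coords = rng.uniform(-50, 50, (15, 3))
        d = euclidean_distance(coords)
        n = 15
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestCommunicability:
    def test_single_edge_closed_form(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = communicability_binary(A)
        assert G[0, 1] == pytest.approx(np.sinh(1.0))
        assert G[0, 0] == pytest.approx(np.cosh(1.0))

    def test_empty_graph_is_identity(self):
        np.testing.assert_allclose(communicability_binary(np.zeros((4, 4))), np.eye(4))

    def test_matches_truncated_walk_series(self, rng):
        for _ in range(10):
            A = (rng.random((8, 8)) < 0.4).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            G = communicability_binary(A)
            import math

            series = sum(np.linalg.matrix_power(A, p) / math.factorial(p) for p in range(31))
            np.testing.assert_allclose(G, series, atol=1e-8)

    def test_weighted_k3_closed_form(self):
        A = np.ones((3, 3)) - np.eye(3)
        G = communicability_weighted(A)
        # strength-normalized K3 has eigenvalues 1, -1/2, -1/2
        expected = (np.e - np.exp(-0.5)) / 3.0
        assert G[0, 1] == pytest.approx(expected)

    def test_regular_graph_reduces_to_scaled_exponential(self):
        A = np.ones((4, 4)) - np.eye(4)  # 3-regular: D = 3I, so G = exp(A/3)
        np.testing.assert_allclose(communicability_weighted(A), expm(A / 3.0))

    def test_zero_strength_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            communicability_weighted(np.zeros((3, 3)))

    def test_edge_addition_monotonicity(self, rng):
        for _ in range(20):
            A = (rng.random((8, 8)) < 0.3).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            G = communicability_binary(A)
            zeros = np.argwhere(np.triu(A == 0, 1))
            if not len(zeros):
                continue
            i, j = zeros[rng.integers(len(zeros))]
            A2 = A.copy()
            A2[i, j] = A2[j, i] = 1.0
            assert np.all(communicability_binary(A2) >= G - 1e-12)

    def test_global_rescaling_invariance(self, rng):
        W = _random_connected_sc(rng, n=8)
        np.testing.assert_allclose(
            communicability_weighted(W), communicability_weighted(3.7 * W), atol=1e-10
        )


class TestExtendedMeasures:
    def test_path_graph_shortest_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        sc = StructuralConnectome(weights=W, coords=np.eye(3))
        ens = extended_measures(sc, measures=("spl_inv",))
        assert ens.measures["spl_inv"][0, 2] == pytest.approx(2.0)

    def test_mfpt_two_node_graph(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        M = mean_first_passage_time(W)
        assert M[0, 1] == pytest.approx(1.0)
        assert M[1, 0] == pytest.approx(1.0)

    def test_search_information_on_forced_path(self):
        # 1-2-3 path: the walk 0->1->2 has prob (1)*(1/2); SI = -log2(1/2) = 1
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        S = search_information(W)
        assert S[0, 2] == pytest.approx(1.0)
        assert S[2, 0] == pytest.approx(1.0)
        assert S[0, 1] == pytest.approx(0.0)  # forced single step

    def test_search_information_path_product_oracle(self, rng):
        """SI equals -log2 of the product of step transition probabilities
        along the reconstructed shortest path."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import dijkstra

        W = _random_connected_sc(rng, n=6, density=0.6)
        S = search_information(W)
        lengths = np.zeros_like(W)
        lengths[W > 0] = 1.0 / W[W > 0]
        _, pred = dijkstra(csr_matrix(lengths), directed=False, return_predecessors=True)
        strength = W.sum(axis=1)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                prob = 1.0
                v = j
                while v != i:
                    u = pred[i, v]
                    prob *= W[u, v] / strength[u]
                    v = u
                assert S[i, j] == pytest.approx(-np.log2(prob), abs=1e-9)

    def test_disconnected_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        sc = StructuralConnectome(weights=W, coords=np.zeros((4, 3)))
        with pytest.raises(ValueError, match="disconnected"):
            extended_measures(sc)

    def test_all_measures_finite_and_symmetric(self, rng):
        W = _random_connected_sc(rng)
        coords = rng.uniform(-50, 50, (12, 3))
        ens = extended_measures(StructuralConnectome(weights=W, coords=coords))
        assert len(ens.measures) == 7
        for name, M in ens.measures.items():
            assert np.all(np.isfinite(M)), name
            np.testing.assert_allclose(M, M.T, atol=1e-9)


class TestCoupling:
    def test_affine_row_gives_unit_r2(self, rng):
        pred = rng.standard_normal((6, 6))
        pred = pred + pred.T
        pattern = 2.0 * pred + 1.0
        assert nodal_r2(pattern, pred, 0) == pytest.approx(1.0)
        assert nodal_r2(-pattern, pred, 0) == pytest.approx(1.0)  # sign-blind

    def test_affine_invariance(self, rng):
        pat = rng.standard_normal((8, 8))
        pred = rng.standard_normal((8, 8))
        base = nodal_r2(pat, pred, 3)
        assert nodal_r2(3 * pat - 2, 0.5 * pred + 7, 3) == pytest.approx(base)

    def test_constant_predictor_row_missing(self):
        pattern = np.arange(16.0).reshape(4, 4)
        assert np.isnan(nodal_r2(pattern, np.ones((4, 4)), 1))

    def test_planted_euclidean_argmax(self, rng):
        coords = rng.uniform(-50, 50, (30, 3))
        d = euclidean_distance(coords)
        pattern = -d + 0.01 * rng.standard_normal((30, 30))
        pattern = (pattern + pattern.T) / 2
        W = _random_connected_sc(rng, n=30)
        ens = extended_measures(StructuralConnectome(weights=W, coords=coords))
        res = coupling_matrix(pattern, ens)
        best, names, hist = max_r2_per_node(res)
        assert np.mean(names == "euclid") >= 0.95
        assert hist.sum() == 30

    def test_null_r2_is_small(self, rng):
        pat = rng.standard_normal((400, 400))
        pat = pat + pat.T
        pred = rng.standard_normal((400, 400))
        pred = pred + pred.T
        vals = [nodal_r2(pat, pred, i) for i in range(100)]
        assert np.mean(np.array(vals) < 0.05) >= 0.9


class TestCouplingAgeTrend:
    def _spins(self, rng, n=120, n_perm=500):
        from eventspan.synthetic import _fibonacci_sphere

        return spin_permutations(_fibonacci_sphere(n), n_perm, seed=rng)

    def test_flat_r2_never_significant(self, rng):
        spins = self._spins(rng, n=60, n_perm=200)
        labels = np.repeat(list("abcdef"), 10)
        R = np.tile(rng.random(60), (5, 1))
        out = coupling_age_trend(R, np.arange(5.0), labels, spins)
        assert not out["significant"].any()

    def test_planted_decline_flagged(self, rng):
        """A steady coupling decline in one system survives the spin null;
        the spun (diluted) trend magnitude cannot match the localized one."""
        spins = self._spins(rng)
        labels = np.repeat(list("abcdefghijkl"), 10)
        R = 0.5 + 0.15 * rng.standard_normal((7, 120))
        R[:, labels == "c"] -= np.linspace(0, 0.6, 7)[:, None]
        flat_ne = 0.5 + 0.15 * rng.standard_normal((7, 120))
        out = coupling_age_trend(
            R, np.arange(7.0), labels, spins, nonevent_r2_per_bin=flat_ne, q=0.05
        )
        assert out.loc[out["system"] == "c", "significant"].item()
        assert out["significant"].sum() <= 3

    def test_stronger_nonevent_trend_vetoes(self, rng):
        spins = self._spins(rng, n=60, n_perm=200)
        labels = np.repeat(list("abcdef"), 10)
        decline = np.linspace(0, 0.4, 5)[:, None]
        R = 0.5 - 0.5 * decline + 0.01 * rng.standard_normal((5, 60))
        ne = 0.5 - 2.0 * decline + 0.01 * rng.standard_normal((5, 60))
        out = coupling_age_trend(R, np.arange(5.0), labels, spins, nonevent_r2_per_bin=ne)
        assert not out["significant"].any()
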