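"""Multiplicative-update NNMF, degeneracy pruning, winner-take-all clustering."""

import numpy as np
import pytest

from bpcurve import (
    degeneracy,
    nnmf_update_step,
    reduce_dimension,
    run_nnmf,
    winner_take_all_clusters,
)


def random_factors(rng, n, q):
    W = rng.random((n, q)) + 0.1
    H = rng.random((q, n)) + 0.1
    norms = np.linalg.norm(H, axis=1)
    return W * norms, H / norms[:, None]


def naive_update(W, H, Xi, eps=1e-12):
    """Scalar-loop re-implementation of one multiplicative update."""
    q, m = H.shape
    n = W.shape[0]
    Hn = H.copy()
    for a in range(q):
        for b in range(m):
            num = sum(W[i, a] * Xi[i, b] for i in range(n))
            den = sum(
                sum(W[i, a] * W[i, c] for i in range(n)) * H[c, b] for c in range(q)
            )
            Hn[a, b] = H[a, b] * num / (den + eps)
    Wn = W.copy()
    for a in range(q):
        norm = np.sqrt(sum(Hn[a, b] ** 2 for b in range(m)))
        if norm > 0:
            for b in range(m):
                Hn[a, b] /= norm
            for i in range(n):
                Wn[i, a] *= norm
    Wout = Wn.copy()
    HHt = Hn @ Hn.T
    for i in range(n):
        for a in range(q):
            num = sum(Xi[i, b] * Hn[a, b] for b in range(m))
            den = sum(Wn[i, c] * HHt[c, a] for c in range(q))
            Wout[i, a] = Wn[i, a] * num / (den + eps)
    return Wout, Hn


class TestUpdateStep:
    def test_exact_factorization_is_a_fixed_point(self, rng):
        W, H = random_factors(rng, 5, 2)
        Xi = W @ H
        W2, H2 = nnmf_update_step(W, H, Xi)
        np.testing.assert_allclose(W2, W, atol=1e-10)
        np.testing.assert_allclose(H2, H, atol=1e-10)

    def test_row_normalization_preserves_product(self, rng):
        """Moving row scale from H into the columns of W leaves WH unchanged."""
        W = rng.random((6, 3))
        H = rng.random((3, 6)) * 10
        norms = np.linalg.norm(H, axis=1)
        W2, H2 = W * norms[None, :], H / norms[:, None]
        assert np.max(np.abs(W2 @ H2 - W @ H)) < 1e-10

    def test_matches_naive_loop_trajectory(self, rng):
        """200 vectorized iterations track a scalar-loop implementation."""
        Xi = rng.random((6, 6))
        W = rng.random((6, 3))
        H = rng.random((3, 6))
        Wn, Hn = W.copy(), H.copy()
        for _ in range(200):
            W, H = nnmf_update_step(W, H, Xi)
            Wn, Hn = naive_update(Wn, Hn, Xi)
        eta_vec = np.linalg.norm(Xi - W @ H) ** 2
        eta_loop = np.linalg.norm(Xi - Wn @ Hn) ** 2
        assert eta_vec == pytest.approx(eta_loop, abs=1e-8)
        np.testing.assert_allclose(W @ H, Wn @ Hn, atol=1e-8)

    def test_preserves_non_negativity(self, rng):
        W, H = rng.random((5, 2)), rng.random((2, 5))
        Xi = rng.random((5, 5))
        for _ in range(50):
            W, H = nnmf_update_step(W, H, Xi)
        assert np.all(W >= 0) and np.all(H >= 0)


class TestRunNNMF:
    def test_error_non_increasing_and_rows_unit_norm(self, rng):
        Xi = rng.random((8, 8))
        res = run_nnmf(Xi, 3, restarts=3, seed=7)
        d = np.diff(res.eta_history)
        assert np.all(d <= 1e-9 * res.eta_history[:-1])
        np.testing.assert_allclose(np.linalg.norm(res.H, axis=1), 1.0, atol=1e-10)
        # eta is recomputable from the parts
        assert res.eta == pytest.approx(np.linalg.norm(Xi - res.W @ res.H) ** 2,
                                        rel=1e-9)

    def test_rank_one_matrix_factorized_exactly(self, rng):
        w = rng.random(7) + 0.2
        h = rng.random(7) + 0.2
        Xi = np.outer(w, h)
        res = run_nnmf(Xi, 1, restarts=5, seed=3, tol=1e-12)
        assert res.eta < 1e-6 * np.linalg.norm(Xi) ** 2

    def test_capacity_never_hurts(self, rng):
        """Best-of-restarts error is non-increasing in the inner dimension."""
        Xi = rng.random((6, 6))
        etas = [run_nnmf(Xi, q, restarts=30, seed=11, tol=1e-9).eta
                for q in range(1, 7)]
        assert np.all(np.diff(etas) <= 1e-6 * np.asarray(etas[:-1]) + 1e-12)

    def test_block_structure_recovered(self):
        Xi = np.zeros((6, 6))
        Xi[:3, :3] = 1.0
        Xi[3:, 3:] = 1.0
        res = run_nnmf(Xi, 2, restarts=10, seed=5)
        support = res.H > 0.1
        rows = {tuple(np.flatnonzero(r)) for r in support}
        assert rows == {(0, 1, 2), (3, 4, 5)}

    def test_fixed_seed_is_bit_reproducible(self, rng):
        Xi = rng.random((6, 6))
        a = run_nnmf(Xi, 3, restarts=4, seed=42)
        b = run_nnmf(Xi, 3, restarts=4, seed=42)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)
        assert a.eta == b.eta and a.restart_index == b.restart_index


class TestDegeneracy:
    def test_orthogonal_rows_give_zero(self):
        H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        assert degeneracy(H) == 0.0

    def test_duplicated_row_gives_one(self):
        h = np.array([0.6, 0.8, 0.0])
        assert degeneracy(np.vstack([h, h])) == pytest.approx(1.0)

    def test_q_one_is_zero(self):
        assert degeneracy(np.ones((1, 5)) / np.sqrt(5)) == 0.0

    def test_matches_pairwise_loop(self, rng):
        H = rng.random((4, 6))
        H /= np.linalg.norm(H, axis=1, keepdims=True)
        expected = max(
            float(H[a] @ H[b]) for a in range(4) for b in range(a + 1, 4)
        )
        assert degeneracy(H) == pytest.approx(expected, abs=1e-12)
        expected_sum = sum(
            float(H[a] @ H[b]) for a in range(4) for b in range(a + 1, 4)
        )
        assert degeneracy(H, metric="sum") == pytest.approx(expected_sum, abs=1e-12)


class TestReduceDimension:
    def test_two_orthogonal_blocks_terminate_at_q_two(self):
        Xi = np.zeros((6, 6))
        Xi[:3, :3] = 1.0
        Xi[3:, 3:] = 1.0
        res = reduce_dimension(Xi, q_start=6, seed=1)
        assert res.q == 2
        assert res.zeta < 0.5

    def test_q_start_one_returns_immediately(self, rng):
        res = reduce_dimension(rng.random((4, 4)), q_start=1, seed=0)
        assert res.q == 1 and res.zeta == 0.0

    def test_single_motif_everywhere_ends_at_q_one(self):
        Xi = np.ones((5, 5))
        res = reduce_dimension(Xi, q_start=5, seed=2)
        assert res.q == 1


class TestWinnerTakeAll:
    def test_above_threshold_column_assigned(self):
        H = np.zeros((2, 20))
        H[0, 0], H[1, 0] = 0.6, 0.4
        H[0, 1:] = 0.5
        a = winner_take_all_clusters(H)
        assert a.cluster_of(0) is not None  # 0.6 > 1/(2*20)

    def test_sub_threshold_column_excluded(self):
        H = np.zeros((2, 20))
        H[0, 0], H[1, 0] = 0.02, 0.01  # 0.02 <= 1/40
        H[0, 1:] = 0.5
        a = winner_take_all_clusters(H)
        assert 0 in a.excluded

    def test_matches_argmax_threshold_oracle(self, rng):
        H = rng.random((4, 12))
        H /= np.linalg.norm(H, axis=1, keepdims=True)
        a = winner_take_all_clusters(H)
        thr = 1.0 / 24
        for col in range(12):
            r = int(np.argmax(H[:, col]))
            if H[r, col] > thr:
                assert a.cluster_of(col) is not None
            else:
                assert col in a.excluded
        # wta matrix keeps only the column maxima
        assert np.all((a.H_wta > 0).sum(axis=0) <= 1)

    def test_clusters_and_excluded_partition_subgroups(self, rng):
        H = rng.random((3, 10))
        H /= np.linalg.norm(H, axis=1, keepdims=True)
        a = winner_take_all_clusters(H)
        everyone = sorted(sum(a.clusters, []) + list(a.excluded))
        assert everyone == list(range(10))
        flat = sum(a.clusters, [])
        assert len(flat) == len(set(flat))  # disjoint

    def test_tie_goes_to_lowest_row_and_order_by_weight(self):
        H = np.array([
            [0.5, 0.5, 0.1],
            [0.5, 0.1, 0.9],
        ])
        a = winner_take_all_clusters(H)
        # column 0 ties -> row 0, which then carries 0.5 + 0.5 = 1.0 total
        # weight vs 0.9 for row 1, so row 0 becomes cluster 0
        assert a.cluster_rows == [0, 1]
        assert a.cluster_of(0) == 0 and a.cluster_of(1) == 0
        assert a.cluster_of(2) == 1
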