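"""Dense and sparse self-attention against brute-force oracles.

The dense branch is checked against an explicit exponent-and-normalize
implementation; the sparse branch against (a) the dense branch at k = N and
(b) a masked-softmax oracle (non-selected logits forced to -inf) built from
an explicit gather of the top-k key/value rows.
"""

import numpy as np
import pytest

from tcrmil.attention import (
    AttentionParams,
    affinity_graph,
    attention_backward,
    attention_forward,
    gather_kv,
    init_attention_params,
    multi_head_self_attention,
    project_qkv,
    scaled_dot_attention,
    softmax,
    sparse_self_attention,
    topk_index,
)


def random_params(d_model, d_proj, h, seed):
    return init_attention_params(d_model, d_proj, h,
                                 np.random.default_rng(seed))


def dense_oracle(Q, K, V, scale):
    """Explicit exponentials/normalization, row by row."""
    out = np.zeros((Q.shape[0], V.shape[1]))
    for i in range(Q.shape[0]):
        logits = np.array([Q[i] @ K[j] / np.sqrt(scale)
                           for j in range(K.shape[0])])
        e = np.exp(logits - logits.max())
        p = e / e.sum()
        out[i] = sum(p[j] * V[j] for j in range(V.shape[0]))
    return out


def masked_dense_oracle(X, params, k):
    """Sparse attention via the dense formula with non-selected logits at
    -inf, selection done per head through explicit topk + gather."""
    Q = X @ params.Wq + params.bq
    K = X @ params.Wk + params.bk
    V = X @ params.Wv + params.bv
    n, dp = Q.shape
    h = params.h
    dh = dp // h
    heads = []
    for a in range(h):
        sl = slice(a * dh, (a + 1) * dh)
        Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
        A = affinity_graph(Qh, Kh)
        I = topk_index(A, k)
        Kg, Vg = gather_kv(Kh, Vh, I)
        out = np.zeros((n, dh))
        for i in range(n):
            logits = Kg[i] @ Qh[i] / np.sqrt(dh)
            e = np.exp(logits - logits.max())
            p = e / e.sum()
            out[i] = p @ Vg[i]
        heads.append(out)
    return np.concatenate(heads, axis=1) @ params.Wa + params.ba


class TestProjections:
    def test_zero_input_zero_bias(self):
        p = random_params(6, 4, 1, 0)
        p.bq[:] = p.bk[:] = p.bv[:] = 0
        Q, K, V = project_qkv(np.zeros((3, 6)), p)
        assert np.all(Q == 0) and np.all(K == 0) and np.all(V == 0)

    def test_identity_weight_reproduces_input(self, rng):
        p = random_params(5, 5, 1, 1)
        p.Wq[:] = np.eye(5)
        p.bq[:] = 0
        X = rng.normal(size=(4, 5))
        Q, _, _ = project_qkv(X, p)
        assert np.allclose(Q, X)

    def test_matches_rowwise_affine_oracle(self, rng):
        p = random_params(14, 10, 1, 2)
        X = rng.normal(size=(5, 14))
        Q, K, V = project_qkv(X, p)
        for i in range(5):
            assert np.allclose(Q[i], X[i] @ p.Wq + p.bq)
            assert np.allclose(K[i], X[i] @ p.Wk + p.bk)
            assert np.allclose(V[i], X[i] @ p.Wv + p.bv)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            project_qkv(rng.normal(size=(3, 7)), random_params(14, 10, 1, 3))


class TestScaledDotAttention:
    def test_single_instance_returns_value(self, rng):
        Q = rng.normal(size=(1, 3))
        K = rng.normal(size=(1, 3))
        V = rng.normal(size=(1, 3))
        assert np.allclose(scaled_dot_attention(Q, K, V), V)

    def test_two_identical_instances_average_values(self, rng):
        q = rng.normal(size=3)
        Q = np.stack([q, q])
        K = np.stack([q, q])
        V = rng.normal(size=(2, 3))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_matches_brute_force_oracle(self, rng):
        Q, K, V = (rng.normal(size=(4, 3)) for _ in range(3))
        assert np.allclose(scaled_dot_attention(Q, K, V, scale=3),
                           dense_oracle(Q, K, V, 3), atol=1e-12)

    def test_softmax_rows_sum_to_one(self, rng):
        z = rng.normal(size=(6, 6)) * 5
        assert np.allclose(softmax(z, axis=1).sum(axis=1), 1.0, atol=1e-6)


class TestMultiHead:
    def test_h1_reduces_to_scaled_dot_plus_projection(self, rng):
        p = random_params(14, 10, 1, 4)
        X = rng.normal(size=(6, 14))
        Q, K, V = project_qkv(X, p)
        expect = scaled_dot_attention(Q, K, V, scale=10) @ p.Wa + p.ba
        assert np.allclose(multi_head_self_attention(X, p), expect, atol=1e-12)

    def test_h2_matches_slice_and_loop_oracle(self, rng):
        p = random_params(14, 10, 2, 5)
        X = rng.normal(size=(5, 14))
        Q, K, V = project_qkv(X, p)
        heads = []
        for a in range(2):
            sl = slice(a * 5, (a + 1) * 5)
            heads.append(dense_oracle(Q[:, sl], K[:, sl], V[:, sl], 5))
        expect = np.concatenate(heads, axis=1) @ p.Wa + p.ba
        assert np.allclose(multi_head_self_attention(X, p), expect, atol=1e-10)

    def test_output_shape_equals_input_shape(self, rng):
        p = random_params(14, 10, 1, 6)
        X = rng.normal(size=(9, 14))
        assert multi_head_self_attention(X, p).shape == (9, 14)

    def test_head_count_must_divide_projection(self):
        with pytest.raises(ValueError):
            init_attention_params(14, 10, 3, np.random.default_rng(0))


class TestAffinityAndTopK:
    def test_orthonormal_self_affinity_is_identity(self):
        Q = np.eye(4)
        assert np.allclose(affinity_graph(Q, Q), np.eye(4))

    def test_matches_dot_product_loop(self, rng):
        Q, K = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
        A = affinity_graph(Q, K)
        for i in range(3):
            for j in range(3):
                assert np.isclose(A[i, j], Q[i] @ K[j])

    def test_generally_asymmetric(self, rng):
        Q, K = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        A = affinity_graph(Q, K)
        assert not np.allclose(A, A.T)

    def test_topk_frozen_example(self):
        A = np.array([[5.0, 1.0, 3.0], [2.0, 6.0, 4.0], [7.0, 0.0, 9.0]])
        assert topk_index(A, 2).tolist() == [[0, 2], [1, 2], [2, 0]]

    def test_topk_full_k_is_permutation(self, rng):
        A = rng.normal(size=(5, 5))
        I = topk_index(A, 5)
        for row in I:
            assert sorted(row.tolist()) == list(range(5))

    def test_topk_tie_rule_ascending_index(self):
        A = np.ones((4, 4))
        assert topk_index(A, 2).tolist() == [[0, 1]] * 4

    def test_topk_out_of_range_rejected(self, rng):
        A = rng.normal(size=(3, 3))
        for bad in (0, 4):
            with pytest.raises(ValueError):
                topk_index(A, bad)

    def test_gather_semantics(self, rng):
        K = rng.normal(size=(4, 3))
        V = rng.normal(size=(4, 3))
        I = np.array([[2, 0], [1, 3], [0, 0], [3, 2]])
        Kg, Vg = gather_kv(K, V, I)
        assert Kg.shape == (4, 2, 3)
        for i in range(4):
            for j in range(2):
                assert np.allclose(Kg[i, j], K[I[i, j]])
                assert np.allclose(Vg[i, j], V[I[i, j]])

    def test_gather_identity_permutation(self, rng):
        K = rng.normal(size=(3, 2))
        I = np.tile(np.arange(3), (3, 1))
        Kg, _ = gather_kv(K, K, I)
        for i in range(3):
            assert np.allclose(Kg[i], K)

    def test_gather_out_of_range_rejected(self, rng):
        K = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            gather_kv(K, K, np.array([[0, 3]]))


class TestSparseAttention:
    @pytest.mark.parametrize("h", [1, 2])
    def test_k_equals_n_matches_dense(self, rng, h):
        p = random_params(14, 10, h, 7)
        X = rng.normal(size=(6, 14))
        dense = multi_head_self_attention(X, p)
        sparse = sparse_self_attention(X, p, k=6)
        assert np.max(np.abs(dense - sparse)) <= 1e-5

    def test_k1_self_attention_returns_projected_values(self, rng):
        # construct Q=K so self-affinity is maximal for every row
        p = random_params(4, 4, 1, 8)
        p.Wq[:] = np.eye(4)
        p.Wk[:] = np.eye(4)
        p.Wv[:] = np.eye(4)
        p.bq[:] = p.bk[:] = p.bv[:] = 0
        X = 3.0 * np.eye(4)  # orthogonal rows: self-affinity strictly maximal
        out = sparse_self_attention(X, p, k=1)
        assert np.allclose(out, X @ p.Wa + p.ba)

    @pytest.mark.parametrize("h", [1, 2])
    def test_matches_masked_dense_oracle(self, rng, h):
        for trial in range(20):
            n = int(rng.integers(2, 9))
            dp = 2 * int(rng.integers(1, 4))
            p = random_params(7, dp, h, 100 + trial)
            X = rng.normal(size=(n, 7))
            for k in range(1, n + 1):
                got = sparse_self_attention(X, p, k)
                want = masked_dense_oracle(X, p, k)
                assert np.max(np.abs(got - want)) < 1e-10

    def test_permutation_equivariance(self, rng):
        p = random_params(14, 10, 1, 9)
        X = rng.normal(size=(7, 14))
        perm = rng.permutation(7)
        for k in (3, 7):
            out = sparse_self_attention(X, p, k)
            out_p = sparse_self_attention(X[perm], p, k)
            assert np.allclose(out_p, out[perm], atol=1e-10)
        dense = multi_head_self_attention(X, p)
        dense_p = multi_head_self_attention(X[perm], p)
        assert np.allclose(dense_p, dense[perm], atol=1e-10)


class TestBackward:
    @pytest.mark.parametrize("h,k", [(1, None), (1, 3), (2, None), (2, 3)])
    def test_gradients_match_finite_differences(self, rng, h, k):
        p = random_params(6, 4, h, 10)
        X = rng.normal(size=(5, 6))
        W_out = rng.normal(size=6)  # reduce output to a scalar loss

        def loss(params):
            out, _ = attention_forward(X, params, k=k)
            return float(np.sum(out @ W_out))

        out, cache = attention_forward(X, p, k=k)
        grads = {}
        dOut = np.tile(W_out, (5, 1))
        dX = attention_backward(dOut, cache, p, grads)

        eps = 1e-6
        for name in ("Wq", "bq", "Wk", "bk", "Wv", "bv", "Wa", "ba"):
            arr = getattr(p, name)
            g = grads["att_" + name]
            for idx in list(np.ndindex(*arr.shape))[::3]:
                old = arr[idx]
                arr[idx] = old + eps
                up = loss(p)
                arr[idx] = old - eps
                dn = loss(p)
                arr[idx] = old
                num = (up - dn) / (2 * eps)
                assert abs(num - g[idx]) < 1e-5 * max(1.0, abs(num))
        for idx in list(np.ndindex(*X.shape))[::3]:
            old = X[idx]
            X[idx] = old + eps
            up = loss(p)
            X[idx] = old - eps
            dn = loss(p)
            X[idx] = old
            num = (up - dn) / (2 * eps)
            assert abs(num - dX[idx]) < 1e-5 * max(1.0, abs(num))
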