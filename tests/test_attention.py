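import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biodann.attention import (
    AttentionModel,
    AttentionParams,
    multi_head,
    project_qkv,
    scaled_dot_attention,
    temporal_encode_predict,
)

from conftest import grad_relative_errors


def random_params(rng, h=2, d=3, d_k=2, pooling="last", use_positional=False):
    return AttentionParams(
        Wq=rng.normal(size=(h, d, d_k)),
        Wk=rng.normal(size=(h, d, d_k)),
        Wv=rng.normal(size=(h, d, d_k)),
        Wo=rng.normal(size=(h * d_k, d)),
        w_out=rng.normal(size=d),
        b_out=np.zeros(1),
        pooling=pooling,
        use_positional=use_positional,
    )


class TestProjections:
    def test_zero_input_gives_zero_projections(self, rng):
        W = rng.normal(size=(3, 2))
        Q, K, V = project_qkv(np.zeros((4, 3)), W, W, W)
        assert not Q.any() and not K.any() and not V.any()

    def test_identity_projections(self, rng):
        X = rng.normal(size=(4, 3))
        I = np.eye(3)
        Q, K, V = project_qkv(X, I, I, I)
        np.testing.assert_array_equal(Q, X)
        np.testing.assert_array_equal(K, X)
        np.testing.assert_array_equal(V, X)

    def test_matches_hand_multiplication(self, rng):
        X = rng.normal(size=(5, 3))
        Wq, Wk, Wv = (rng.normal(size=(3, 2)) for _ in range(3))
        Q, K, V = project_qkv(X, Wq, Wk, Wv)
        np.testing.assert_allclose(Q, X @ Wq, atol=1e-12)
        np.testing.assert_allclose(K, X @ Wk, atol=1e-12)
        np.testing.assert_allclose(V, X @ Wv, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            project_qkv(np.zeros((4, 3)), np.zeros((2, 2)), np.zeros((3, 2)),
                        np.zeros((3, 2)))


class TestScaledDotAttention:
    def test_single_step_is_identity_on_v(self, rng):
        V = rng.normal(size=(1, 3))
        out, A = scaled_dot_attention(rng.normal(size=(1, 2)),
                                      rng.normal(size=(1, 2)), V, d_k=2)
        np.testing.assert_allclose(A, [[1.0]])
        np.testing.assert_allclose(out, V)

    def test_zero_keys_give_uniform_rows(self, rng):
        T = 5
        V = rng.normal(size=(T, 2))
        out, A = scaled_dot_attention(rng.normal(size=(T, 2)), np.zeros((T, 2)),
                                      V, d_k=2)
        np.testing.assert_allclose(A, np.full((T, T), 1 / T))
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (T, 1)))

    def test_hand_computed_scalar_case(self):
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0], [0.0]])
        out, A = scaled_dot_attention(Q, K, V, d_k=2)
        logits = np.array([1 / np.sqrt(2), 0.0])
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(A[0], expected, rtol=1e-12)
        assert out[0, 0] == pytest.approx(expected[0], rel=1e-9)
        assert out[0, 0] == pytest.approx(0.6698, abs=1e-4)

    def test_invalid_dk_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 2)), np.zeros((2, 2)),
                                 np.zeros((2, 1)), d_k=0)

    def test_huge_logits_stay_finite(self):
        Q = np.full((3, 2), 1e4)
        K = np.full((3, 2), 1e4)
        V = np.ones((3, 2))
        out, A = scaled_dot_attention(Q, K, V, d_k=2)
        assert np.all(np.isfinite(out)) and np.all(np.isfinite(A))
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)


class TestMultiHead:
    def test_single_head_identity_wo_reduces(self, rng):
        d = d_k = 3
        Wq, Wk, Wv = (rng.normal(size=(1, d, d_k)) for _ in range(3))
        params = AttentionParams(Wq=Wq, Wk=Wk, Wv=Wv, Wo=np.eye(d),
                                 w_out=np.zeros(d), b_out=np.zeros(1))
        X = rng.normal(size=(4, d))
        Q, K, V = project_qkv(X, Wq[0], Wk[0], Wv[0])
        single, _ = scaled_dot_attention(Q, K, V, d_k)
        np.testing.assert_allclose(multi_head(X, params).output, single, atol=1e-12)

    def test_duplicated_head_with_selecting_wo(self, rng):
        d = d_k = 2
        W = rng.normal(size=(1, d, d_k))
        Wq = np.concatenate([W, W])
        params = AttentionParams(
            Wq=Wq, Wk=Wq, Wv=Wq,
            Wo=np.vstack([np.eye(d), np.zeros((d, d))]),
            w_out=np.zeros(d), b_out=np.zeros(1),
        )
        X = rng.normal(size=(5, d))
        Q, K, V = project_qkv(X, Wq[0], Wq[0], Wq[0])
        single, _ = scaled_dot_attention(Q, K, V, d_k)
        np.testing.assert_allclose(multi_head(X, params).output, single, atol=1e-12)

    def test_matches_naive_loop_reference(self, rng):
        params = random_params(rng, h=2, d=3, d_k=2)
        X = rng.normal(size=(6, 3))
        got = multi_head(X, params).output
        # independent naive composition
        heads = []
        for i in range(2):
            S = (X @ params.Wq[i]) @ (X @ params.Wk[i]).T / np.sqrt(2)
            E = np.exp(S - S.max(axis=1, keepdims=True))
            A = E / E.sum(axis=1, keepdims=True)
            heads.append(A @ (X @ params.Wv[i]))
        expected = np.hstack(heads) @ params.Wo
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_wo_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            AttentionParams(
                Wq=np.zeros((2, 3, 2)), Wk=np.zeros((2, 3, 2)),
                Wv=np.zeros((2, 3, 2)), Wo=np.zeros((5, 3)),
                w_out=np.zeros(3), b_out=np.zeros(1),
            )


class TestEncodePredict:
    def test_constant_window_mean_pooling(self, rng):
        params = random_params(rng, pooling="mean")
        row = rng.normal(size=3)
        X = np.tile(row, (7, 1))
        pred = temporal_encode_predict(X, params)
        # with identical rows every attended row equals the encoded row itself
        enc = multi_head(X, params).output
        np.testing.assert_allclose(enc, np.tile(enc[0], (7, 1)), atol=1e-10)
        assert pred == pytest.approx(float(enc[0] @ params.w_out), abs=1e-10)

    def test_zero_weights_return_bias(self, rng):
        params = random_params(rng)
        params.Wo = np.zeros_like(params.Wo)
        params.w_out = np.zeros_like(params.w_out)
        params.b_out = np.array([2.5])
        assert temporal_encode_predict(rng.normal(size=(4, 3)), params) == 2.5

    def test_matches_hand_composed_chain(self, rng):
        params = random_params(rng, h=2, d=3, d_k=2, pooling="last")
        X = rng.normal(size=(5, 3))
        enc = multi_head(X, params).output
        expected = float(enc[-1] @ params.w_out + params.b_out[0])
        assert temporal_encode_predict(X, params) == pytest.approx(expected, rel=1e-12)

    def test_batched_model_matches_single_window(self, rng):
        params = random_params(rng, h=2, d=3, d_k=2)
        model = AttentionModel(params)
        X = rng.normal(size=(4, 6, 3))
        batched = model.predict(X)
        singles = [temporal_encode_predict(X[i], params) for i in range(4)]
        np.testing.assert_allclose(batched, singles, atol=1e-12)


class TestInvariants:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_rows_stochastic_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        T, d, d_k = rng.integers(2, 8), rng.integers(1, 5), rng.integers(1, 5)
        Q = rng.normal(scale=3, size=(T, d_k))
        K = rng.normal(scale=3, size=(T, d_k))
        V = rng.normal(scale=3, size=(T, d))
        out, A = scaled_dot_attention(Q, K, V, d_k)
        assert np.all(A >= 0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)
        for j in range(d):
            assert np.all(out[:, j] >= V[:, j].min() - 1e-12)
            assert np.all(out[:, j] <= V[:, j].max() + 1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_permutation_equivariance_without_positions(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, h=2, d=3, d_k=2, pooling="mean")
        X = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        out = multi_head(X, params).output
        out_perm = multi_head(X[perm], params).output
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)
        # mean-pooled prediction is permutation invariant
        assert temporal_encode_predict(X[perm], params) == pytest.approx(
            temporal_encode_predict(X, params), abs=1e-10
        )


class TestGradients:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_gradients_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        pooling = "last" if seed % 2 else "mean"
        model = AttentionModel.create(d=3, h=2, d_k=2, pooling=pooling, seed=seed)
        X = rng.normal(size=(3, 5, 3))
        y = rng.normal(size=3)
        errs = grad_relative_errors(model, X, y)
        assert max(errs) <= 1e-5

    def test_positional_encoding_breaks_permutation_invariance(self, rng):
        model = AttentionModel.create(d=3, h=2, d_k=2, pooling="mean",
                                      use_positional=True, seed=0)
        X = rng.normal(size=(1, 6, 3))
        X_rev = X[:, ::-1, :]
        assert model.predict(X)[0] != pytest.approx(model.predict(X_rev)[0])
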