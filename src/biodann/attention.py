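"""Multi-head scaled-dot-product attention encoder for window regression.

For a window X in R^(T x d), each head projects X into query/key/value
subspaces (Q = X W^Q, K = X W^K, V = X W^V, all d x d_k), computes the
row-stochastic attention matrix A = softmax(Q K^T / sqrt(d_k)) and its
attended values A V; head outputs are concatenated and mapped back to d
dimensions by W^O.  The encoded window is pooled over time (last time step
by default, mean optionally) and an affine head produces the scalar
next-step prediction.

There is no positional encoding by default — the encoder as specified is
permutation-equivariant in time — but a sinusoidal encoding can be switched
on.  The model exposes the same trainable-model protocol as the feed-forward
network, so :func:`biodann.dnn.train` trains it unchanged; gradients are
exact reverse-mode derivatives (validated against finite differences in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionParams",
    "AttentionOutput",
    "AttentionModel",
    "project_qkv",
    "scaled_dot_attention",
    "multi_head",
    "temporal_encode_predict",
    "positional_encoding",
]


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class AttentionParams:
    """Projection matrices and prediction head of the attention encoder.

    ``Wq``/``Wk``/``Wv`` have shape (h, d, d_k); ``Wo`` has shape
    (h*d_k, d); ``w_out`` (d,) and ``b_out`` form the affine prediction head.
    """

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    Wo: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray  # shape (1,) so the training loop can update in place
    pooling: str = "last"
    use_positional: bool = False

    def __post_init__(self) -> None:
        for name in ("Wq", "Wk", "Wv", "Wo", "w_out", "b_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.Wq.ndim != 3 or not (self.Wq.shape == self.Wk.shape == self.Wv.shape):
            raise ValueError("Wq, Wk, Wv must share shape (h, d, d_k)")
        h, d, d_k = self.Wq.shape
        if h < 1 or d_k < 1:
            raise ValueError("need h >= 1 and d_k >= 1")
        if self.Wo.shape != (h * d_k, d):
            raise ValueError(
                f"Wo must have shape ({h * d_k}, {d}), got {self.Wo.shape}"
            )
        if self.w_out.shape != (d,):
            raise ValueError(f"w_out must have shape ({d},)")
        self.b_out = self.b_out.reshape(1)
        if self.pooling not in ("last", "mean"):
            raise ValueError("pooling must be 'last' or 'mean'")

    @property
    def h(self) -> int:
        return self.Wq.shape[0]

    @property
    def d(self) -> int:
        return self.Wq.shape[1]

    @property
    def d_k(self) -> int:
        return self.Wq.shape[2]


@dataclass
class AttentionOutput:
    """Encoded window plus the per-head attention matrices."""

    output: np.ndarray  # (T, d)
    attention_matrices: np.ndarray  # (h, T, T), each row sums to 1


def positional_encoding(T: int, d: int) -> np.ndarray:
    """Standard sinusoidal positional encoding, shape (T, d)."""
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def project_qkv(
    X: np.ndarray, Wq: np.ndarray, Wk: np.ndarray, Wv: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-head linear projections Q = X Wq, K = X Wk, V = X Wv."""
    X = np.asarray(X, dtype=float)
    for W in (Wq, Wk, Wv):
        if X.shape[-1] != np.asarray(W).shape[0]:
            raise ValueError("projection matrix rows must match feature dim of X")
    return X @ Wq, X @ Wk, X @ Wv


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Attention output ``softmax(Q K^T / sqrt(d_k)) V`` and the matrix A.

    Softmax is computed with per-row max subtraction, so logits of large
    magnitude stay finite.  Every row of A is a probability vector, hence
    each output row is a convex combination of V's rows.
    """
    if d_k <= 0:
        raise ValueError("d_k must be > 0")
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share their column dimension")
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must share their row count")
    A = _softmax_rows(Q @ K.T / np.sqrt(d_k))
    return A @ V, A


def multi_head(X: np.ndarray, params: AttentionParams) -> AttentionOutput:
    """Concat per-head attended values along features, then apply W^O."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty (T, d) matrix")
    if X.shape[1] != params.d:
        raise ValueError(f"X feature dim {X.shape[1]} != model dim {params.d}")
    heads, mats = [], []
    for i in range(params.h):
        Q, K, V = project_qkv(X, params.Wq[i], params.Wk[i], params.Wv[i])
        out, A = scaled_dot_attention(Q, K, V, params.d_k)
        heads.append(out)
        mats.append(A)
    concat = np.concatenate(heads, axis=1)  # (T, h*d_k)
    return AttentionOutput(
        output=concat @ params.Wo, attention_matrices=np.stack(mats)
    )


def temporal_encode_predict(X: np.ndarray, params: AttentionParams) -> float:
    """Encode one window and return the scalar next-step prediction."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty (T, d) matrix")
    if params.use_positional:
        X = X + positional_encoding(X.shape[0], X.shape[1])
    enc = multi_head(X, params).output
    pooled = enc[-1] if params.pooling == "last" else enc.mean(axis=0)
    return float(pooled @ params.w_out + params.b_out[0])


class AttentionModel:
    """Trainable wrapper exposing the shared model protocol.

    Forward/backward passes are vectorised over the batch with einsum so
    minibatch training over thousands of windows stays fast on one CPU.
    """

    def __init__(self, params: AttentionParams):
        self.params = params

    @classmethod
    def create(
        cls,
        d: int,
        h: int = 4,
        d_k: int = 16,
        pooling: str = "last",
        use_positional: bool = False,
        seed: int = 0,
    ) -> "AttentionModel":
        rng = np.random.default_rng(seed)

        def init(*shape):
            limit = np.sqrt(6.0 / shape[-2])
            return rng.uniform(-limit, limit, size=shape)

        params = AttentionParams(
            Wq=init(h, d, d_k),
            Wk=init(h, d, d_k),
            Wv=init(h, d, d_k),
            Wo=init(h * d_k, d),
            w_out=rng.uniform(-np.sqrt(6.0 / d), np.sqrt(6.0 / d), size=d),
            b_out=np.zeros(1),
            pooling=pooling,
            use_positional=use_positional,
        )
        return cls(params)

    # --- trainable-model protocol -------------------------------------
    def parameters(self) -> list[np.ndarray]:
        p = self.params
        return [p.Wq, p.Wk, p.Wv, p.Wo, p.w_out, p.b_out]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n, T, d) or (T, d)")
        if X.shape[2] != self.params.d:
            raise ValueError("feature dim mismatch")
        if self.params.use_positional:
            X = X + positional_encoding(X.shape[1], X.shape[2])
        return X

    def _forward(self, X: np.ndarray):
        p = self.params
        scale = 1.0 / np.sqrt(p.d_k)
        Q = np.einsum("ntd,hdk->hntk", X, p.Wq)
        K = np.einsum("ntd,hdk->hntk", X, p.Wk)
        V = np.einsum("ntd,hdk->hntk", X, p.Wv)
        A = _softmax_rows(np.einsum("hntk,hnsk->hnts", Q, K) * scale)
        H = np.einsum("hnts,hnsk->hntk", A, V)  # (h, n, T, d_k)
        n, T = X.shape[0], X.shape[1]
        concat = H.transpose(1, 2, 0, 3).reshape(n, T, p.h * p.d_k)
        O = concat @ p.Wo  # (n, T, d)
        pooled = O[:, -1, :] if p.pooling == "last" else O.mean(axis=1)
        pred = pooled @ p.w_out + p.b_out[0]
        return pred, (X, Q, K, V, A, concat, O, pooled)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(self._prepare(X))[0]

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        p = self.params
        X = self._prepare(X)
        y = np.asarray(y, dtype=float).ravel()
        pred, cache = self._forward(X)
        Xc, Q, K, V, A, concat, O, pooled = cache
        n, T = Xc.shape[0], Xc.shape[1]
        resid = pred - y
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss in attention forward pass")

        dpred = 2.0 * resid / n  # (n,)
        db_out = np.array([dpred.sum()])
        dw_out = pooled.T @ dpred
        dpooled = np.outer(dpred, p.w_out)  # (n, d)
        dO = np.zeros_like(O)
        if p.pooling == "last":
            dO[:, -1, :] = dpooled
        else:
            dO += dpooled[:, None, :] / T
        dWo = np.einsum("ntm,ntd->md", concat, dO)
        dconcat = dO @ p.Wo.T  # (n, T, h*d_k)
        dH = dconcat.reshape(n, T, p.h, p.d_k).transpose(2, 0, 1, 3)

        dA = np.einsum("hntk,hnsk->hnts", dH, V)
        dV = np.einsum("hnts,hntk->hnsk", A, dH)
        # softmax backward per row
        dS = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(p.d_k)
        dQ = np.einsum("hnts,hnsk->hntk", dS, K) * scale
        dK = np.einsum("hnts,hntk->hnsk", dS, Q) * scale

        dWq = np.einsum("ntd,hntk->hdk", Xc, dQ)
        dWk = np.einsum("ntd,hntk->hdk", Xc, dK)
        dWv = np.einsum("ntd,hntk->hdk", Xc, dV)
        return loss, [dWq, dWk, dWv, dWo, dw_out, db_out]
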