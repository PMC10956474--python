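"""Dense and content-based sparse self-attention over repertoire features.

The repertoire feature matrix ``X`` (one row per TCR, D=14 features) is
projected to query/key/value matrices, and two attention branches share those
projections:

* **dense multi-head self-attention** — every TCR attends to every TCR with
  softmax(Q K^T / sqrt(d_head)) weights;
* **content-based sparse self-attention** — a TCR-to-TCR affinity graph
  ``A = Q K^T`` is pruned to each row's top-k entries, and every TCR attends
  only to its k most related TCRs.

Both branches end with the same output projection ``W_A, b_A`` back to D
dimensions, which is what makes the self-contrastive comparison of their
outputs meaningful.  Sparse attention is computed here as dense attention
with the non-selected logits masked to -inf, which is algebraically identical
to gathering the k selected key/value rows and running attention on the
gathered set, and makes the backward pass uniform across branches.

All forward/backward passes are plain numpy; gradients are derived
analytically (the top-k index selection is treated as locally constant, as
usual for discrete routing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttentionParams:
    """Shared projection weights for the dense and sparse branches."""

    Wq: np.ndarray
    bq: np.ndarray
    Wk: np.ndarray
    bk: np.ndarray
    Wv: np.ndarray
    bv: np.ndarray
    Wa: np.ndarray  # output projection D' -> D
    ba: np.ndarray
    h: int = 1

    @property
    def d_model(self) -> int:
        return self.Wq.shape[0]

    @property
    def d_proj(self) -> int:
        return self.Wq.shape[1]

    def validate(self) -> None:
        if self.d_proj % self.h != 0:
            raise ValueError(
                f"head count {self.h} does not divide D'={self.d_proj}")


def init_attention_params(
    d_model: int, d_proj: int, h: int, rng: np.random.Generator
) -> AttentionParams:
    """Glorot-uniform initialization of all projection weights, zero biases."""
    if d_proj % h != 0:
        raise ValueError(f"head count {h} does not divide D'={d_proj}")

    def glorot(n_in, n_out):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    return AttentionParams(
        Wq=glorot(d_model, d_proj), bq=np.zeros(d_proj),
        Wk=glorot(d_model, d_proj), bk=np.zeros(d_proj),
        Wv=glorot(d_model, d_proj), bv=np.zeros(d_proj),
        Wa=glorot(d_proj, d_model), ba=np.zeros(d_model),
        h=h,
    )


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; rows that are entirely -inf would be
    invalid and are not produced by any caller (k >= 1)."""
    m = np.max(z, axis=axis, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=axis, keepdims=True)


def project_qkv(
    X: np.ndarray, params: AttentionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine projections Q = X Wq + bq (likewise K, V)."""
    if X.ndim != 2 or X.shape[1] != params.d_model:
        raise ValueError(
            f"X has shape {X.shape}, expected (*, {params.d_model})")
    Q = X @ params.Wq + params.bq
    K = X @ params.Wk + params.bk
    V = X @ params.Wv + params.bv
    return Q, K, V


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, scale: float | None = None
) -> np.ndarray:
    """Single-head scaled dot-product attention softmax(Q K^T / sqrt(scale)) V.

    ``scale`` defaults to the key dimension.
    """
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ValueError("non-conforming Q/K/V shapes")
    scale = float(K.shape[1]) if scale is None else float(scale)
    P = softmax(Q @ K.T / np.sqrt(scale), axis=1)
    return P @ V


def affinity_graph(Q: np.ndarray, K: np.ndarray) -> np.ndarray:
    """TCR-to-TCR affinity graph A = Q K^T (unscaled, pre-softmax)."""
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K have different projection dimensions")
    return Q @ K.T


def topk_index(A: np.ndarray, k: int) -> np.ndarray:
    """Row-wise indices of the k largest affinities.

    Row i lists the indices of the k largest entries of A[i, :], ordered by
    descending value with exact ties broken by ascending index.  A TCR's
    self-affinity is eligible like any other entry.
    """
    n = A.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    # stable argsort of -A: descending values, ties by ascending index
    return np.argsort(-A, axis=1, kind="stable")[:, :k]


def gather_kv(
    K: np.ndarray, V: np.ndarray, I: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gather per-query key/value sets: output (N, k, D') with
    ``K_g[i, j] = K[I[i, j]]``."""
    if I.min() < 0 or I.max() >= K.shape[0]:
        raise ValueError("gather index out of range")
    return K[I], V[I]


# ---------------------------------------------------------------------------
# Fused forward/backward used by the model
# ---------------------------------------------------------------------------

def _heads(M: np.ndarray, h: int) -> np.ndarray:
    """Split (N, D') into h contiguous slices -> (N, h, d_head)."""
    n, dp = M.shape
    return M.reshape(n, h, dp // h)


def attention_forward(
    X: np.ndarray, params: AttentionParams, k: int | None = None
) -> tuple[np.ndarray, dict]:
    """One attention branch: dense when ``k`` is None, sparse top-k otherwise.

    Returns the projected output (N, D) and a cache for the backward pass.
    Top-k selection happens per head on that head's slice of the affinity
    graph; selection order is value-descending with ascending-index ties.
    """
    params.validate()
    n = X.shape[0]
    Q, K, V = project_qkv(X, params)
    h = params.h
    dh = params.d_proj // h
    Qh, Kh, Vh = _heads(Q, h), _heads(K, h), _heads(V, h)
    S = np.einsum("nhd,mhd->hnm", Qh, Kh) / np.sqrt(dh)
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError(f"k={k} out of range [1, {n}]")
        # top-k per head; scaling is monotone so selection matches Eq A=QK^T
        idx = np.argsort(-S, axis=2, kind="stable")[:, :, :k]
        mask = np.zeros_like(S, dtype=bool)
        np.put_along_axis(mask, idx, True, axis=2)
        S = np.where(mask, S, -np.inf)
    P = softmax(S, axis=2)  # (h, n, n)
    O = np.einsum("hnm,mhd->nhd", P, Vh).reshape(n, params.d_proj)
    out = O @ params.Wa + params.ba
    cache = {"X": X, "Qh": Qh, "Kh": Kh, "Vh": Vh, "P": P, "O": O, "dh": dh}
    return out, cache


def attention_backward(
    dOut: np.ndarray,
    cache: dict,
    params: AttentionParams,
    grads: dict[str, np.ndarray],
    prefix: str = "att_",
) -> np.ndarray:
    """Backward pass of one branch; accumulates parameter grads, returns dX.

    The same code serves the dense and the sparse branch: masked logits have
    zero softmax probability, hence zero gradient, automatically.
    """
    X, P = cache["X"], cache["P"]
    Qh, Kh, Vh = cache["Qh"], cache["Kh"], cache["Vh"]
    n = X.shape[0]
    h, dh = params.h, cache["dh"]

    def acc(name, g):
        grads[name] = grads.get(name, 0) + g

    acc(prefix + "Wa", cache["O"].T @ dOut)
    acc(prefix + "ba", dOut.sum(axis=0))
    dO = (dOut @ params.Wa.T).reshape(n, h, dh)

    dV = np.einsum("hnm,nhd->mhd", P, dO)
    dP = np.einsum("nhd,mhd->hnm", dO, Vh)
    dS = P * (dP - np.sum(dP * P, axis=2, keepdims=True))
    scale = 1.0 / np.sqrt(dh)
    dQ = np.einsum("hnm,mhd->nhd", dS, Kh) * scale
    dK = np.einsum("hnm,nhd->mhd", dS, Qh) * scale

    dQ = dQ.reshape(n, -1)
    dK = dK.reshape(n, -1)
    dV = dV.reshape(n, -1)
    acc(prefix + "Wq", X.T @ dQ)
    acc(prefix + "bq", dQ.sum(axis=0))
    acc(prefix + "Wk", X.T @ dK)
    acc(prefix + "bk", dK.sum(axis=0))
    acc(prefix + "Wv", X.T @ dV)
    acc(prefix + "bv", dV.sum(axis=0))
    return dQ @ params.Wq.T + dK @ params.Wk.T + dV @ params.Wv.T


# ---------------------------------------------------------------------------
# Public convenience wrappers
# ---------------------------------------------------------------------------

def multi_head_self_attention(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Dense multi-head self-attention with output projection: (N, D) -> (N, D)."""
    out, _ = attention_forward(X, params, k=None)
    return out


def sparse_self_attention(X: np.ndarray, params: AttentionParams, k: int) -> np.ndarray:
    """Content-based sparse self-attention: each TCR attends to its top-k
    affinity neighbours only; same parameters and output projection as the
    dense branch, so k = N reproduces it exactly."""
    out, _ = attention_forward(X, params, k=k)
    return out
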