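"""Per-TCR antigen-specificity features from multi-width convolutions.

Each CDR3 embedding (``l x d``) is scanned by 14 convolutional filters whose
widths span the short-motif range (default: widths 2-8, two filters per
width).  A ReLU and 1-max pooling over the *valid* (unpadded) windows reduce
each filter map to a scalar, and concatenating the 14 scalars yields one
feature row per TCR; a repertoire of N TCRs becomes an ``N x 14`` matrix.
The argmax window of each pooled maximum is recorded so trained filters can
later be mapped back to the CDR3 subsequence (motif) they responded to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_WIDTHS = (2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 8)


@dataclass
class FeatureExtractorConfig:
    """Filter bank layout: widths (14 total by default), input depth, activation."""

    filter_widths: tuple = DEFAULT_WIDTHS
    d_in: int = 15
    activation: str = "relu"

    @property
    def n_filters(self) -> int:
        return len(self.filter_widths)

    def distinct_widths(self) -> list[int]:
        return sorted(set(self.filter_widths))

    def validate(self, min_length: int = 10) -> None:
        if max(self.filter_widths) > min_length:
            raise ValueError("a filter is wider than the minimum CDR3 length")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class RepertoireFeatureMatrix:
    """``N x F`` per-TCR features plus the pooled argmax positions."""

    X: np.ndarray
    pool_positions: np.ndarray
    tcr_index: list = field(default_factory=list)


def init_conv_params(
    cfg: FeatureExtractorConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Glorot-uniform filter weights grouped by width, zero biases.

    Parameter dict keys: ``conv_W{w}`` of shape (n_filters_of_width_w, w, d)
    and ``conv_b{w}`` of shape (n_filters_of_width_w,).
    """
    params = {}
    for w in cfg.distinct_widths():
        n_f = cfg.filter_widths.count(w)
        fan_in = w * cfg.d_in
        limit = np.sqrt(6.0 / (fan_in + 1))
        params[f"conv_W{w}"] = rng.uniform(-limit, limit, size=(n_f, w, cfg.d_in))
        params[f"conv_b{w}"] = np.zeros(n_f)
    return params


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    return z


def convolve_1d(
    tm,
    weights: np.ndarray,
    bias: float = 0.0,
    activation: str = "relu",
) -> np.ndarray:
    """Valid-window 1-D convolution of one TCR matrix with a single w x d filter.

    ``tm`` may be a :class:`~tcrmil.preprocess.TCRMatrix` (padded rows are
    excluded via its valid_length) or a bare ``l x d`` array.  Output length
    is ``valid_length - w + 1``.
    """
    values = getattr(tm, "values", tm)
    l = getattr(tm, "valid_length", values.shape[0])
    w = weights.shape[0]
    if w > l:
        raise ValueError(f"filter width {w} exceeds sequence length {l}")
    windows = sliding_window_view(values[:l], w, axis=0)  # (l-w+1, d, w)
    z = np.einsum("pdw,wd->p", windows, weights) + bias
    return _activate(z, activation)


def max_pool_1(act: np.ndarray) -> tuple[float, int]:
    """1-max pooling: (max value, smallest argmax index)."""
    act = np.asarray(act)
    if act.size == 0:
        raise ValueError("cannot max-pool an empty activation vector")
    pos = int(np.argmax(act))  # argmax returns the first maximum
    return float(act[pos]), pos


def extract_features(
    encoded: np.ndarray,
    lengths: np.ndarray,
    cfg: FeatureExtractorConfig,
    params: dict[str, np.ndarray],
) -> RepertoireFeatureMatrix:
    """Feature matrix X (``n x n_filters``) for one encoded repertoire.

    Vectorized over TCRs and filters; windows that would overlap zero padding
    are masked out of the pooling, so features are padding-invariant.
    """
    out = _forward_features(encoded, lengths, cfg, params)
    return RepertoireFeatureMatrix(X=out["X"], pool_positions=out["pos"])


def _forward_features(
    encoded: np.ndarray,
    lengths: np.ndarray,
    cfg: FeatureExtractorConfig,
    params: dict[str, np.ndarray],
) -> dict:
    """Forward pass with caches needed for the backward pass.

    Returns X (n, F), pos (n, F) argmax window starts, and per-width caches
    (pre-activation value at the pooled window).
    """
    n, l_max, _ = encoded.shape
    n_f_total = cfg.n_filters
    X = np.zeros((n, n_f_total))
    pos = np.zeros((n, n_f_total), dtype=int)
    zstar = np.zeros((n, n_f_total))  # pre-activation at pooled position
    col = _width_column_map(cfg)
    for w in cfg.distinct_widths():
        if f"conv_W{w}" not in params:
            raise ValueError(f"parameter set lacks conv_W{w} for the "
                             f"configured filter bank")
        W = params[f"conv_W{w}"]  # (nf, w, d)
        b = params[f"conv_b{w}"]
        p_w = l_max - w + 1
        windows = sliding_window_view(encoded, w, axis=1)  # (n, p_w, d, w)
        z = np.einsum("npdw,fwd->npf", windows, W) + b  # (n, p_w, nf)
        a = _activate(z, cfg.activation)
        valid = np.arange(p_w)[None, :] <= (lengths - w)[:, None]  # (n, p_w)
        a_masked = np.where(valid[:, :, None], a, -np.inf)
        p_star = np.argmax(a_masked, axis=1)  # (n, nf) first max
        rows = np.arange(n)[:, None]
        X[:, col[w]] = a[rows, p_star, np.arange(len(b))[None, :]]
        pos[:, col[w]] = p_star
        zstar[:, col[w]] = z[rows, p_star, np.arange(len(b))[None, :]]
    return {"X": X, "pos": pos, "zstar": zstar, "encoded": encoded,
            "lengths": lengths}


def _width_column_map(cfg: FeatureExtractorConfig) -> dict[int, np.ndarray]:
    """Feature-column indices of each distinct width, in config filter order."""
    widths = np.array(cfg.filter_widths)
    return {w: np.where(widths == w)[0] for w in sorted(set(cfg.filter_widths))}


def _backward_features(
    dX: np.ndarray,
    cache: dict,
    cfg: FeatureExtractorConfig,
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate filter gradients given dL/dX.

    Gradient flows only through each filter's pooled (argmax) window; with
    ReLU it is zero where the pooled pre-activation is negative.
    """
    encoded = cache["encoded"]
    n = encoded.shape[0]
    col = _width_column_map(cfg)
    rows = np.arange(n)
    for w in cfg.distinct_widths():
        cols = col[w]
        g = dX[:, cols]  # (n, nf)
        if cfg.activation == "relu":
            g = g * (cache["zstar"][:, cols] > 0)
        p_star = cache["pos"][:, cols]  # (n, nf)
        gW = np.zeros_like(params[f"conv_W{w}"])
        gb = g.sum(axis=0)
        # windows at the pooled positions: (n, nf, w, d)
        for j in range(len(cols)):
            win = encoded[rows[:, None], p_star[:, j:j + 1] + np.arange(w)[None, :], :]
            gW[j] = np.einsum("n,nwd->wd", g[:, j], win)
        grads[f"conv_W{w}"] = grads.get(f"conv_W{w}", 0) + gW
        grads[f"conv_b{w}"] = grads.get(f"conv_b{w}", 0) + gb
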