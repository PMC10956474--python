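"""Full multi-instance model: motif features -> attention -> decision layer.

One repertoire (a bag of up to N CDR3s) flows through

1. the convolutional motif-feature extractor, giving ``X`` (n x 14);
2. row dropout on ``X`` (train mode only, rate 0.4);
3. two attention branches sharing one parameter set: content-based sparse
   top-k self-attention (k = max(1, floor(k_r * n))) feeding the decision
   layer, and dense multi-head self-attention used only as the reference of
   the self-contrastive loss;
4. a linear + sigmoid decision layer giving per-TCR probabilities
   ``y_i = sigmoid(O^CSA' W_D + b_D)`` and the repertoire probability
   ``Y = mean(y)``, with the strict decision rule ``Y > 0.5 => cancer``.

Training minimizes ``L = L_M + lambda * L_C`` where ``L_M`` is binary
cross-entropy on the repertoire probability and ``L_C`` the mean squared
discrepancy between the sparse and dense branch outputs.  All gradients are
analytic numpy; the whole parameter set lives in one flat dict so the
optimizer and checkpointing stay trivial.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field

import numpy as np

from .attention import (
    AttentionParams,
    attention_backward,
    attention_forward,
    init_attention_params,
)
from .motif_features import (
    FeatureExtractorConfig,
    _backward_features,
    _forward_features,
    init_conv_params,
)
from .preprocess import MAX_LENGTH, Repertoire, default_aa_factors, encode_repertoire

EPS = 1e-7  # probability clamp for the cross-entropy loss

VARIANTS = ("full", "no_contrastive", "dense_only", "no_attention")


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setting:
    N=100 selected TCRs, D'=10, one head, k_r=0.05, dropout 0.4)."""

    n_top: int = 100
    d_feat: int = 14
    d_proj: int = 10
    h: int = 1
    k_r: float = 0.05
    dropout: float = 0.4
    lam: float = 1.0
    variant: str = "full"
    filter_widths: tuple = (2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 8)
    d_in: int = 15
    l_max: int = MAX_LENGTH

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; pick from {VARIANTS}")
        if len(self.filter_widths) != self.d_feat:
            raise ValueError("filter count must equal the feature dimension")

    def feature_config(self) -> FeatureExtractorConfig:
        return FeatureExtractorConfig(
            filter_widths=tuple(self.filter_widths), d_in=self.d_in)

    def k_for(self, n: int) -> int:
        return max(1, int(np.floor(self.k_r * n)))


@dataclass
class PredictionScores:
    """Per-TCR probabilities, repertoire probability, and the hard label."""

    y_tilde: np.ndarray
    Y_tilde: float
    label_pred: int


@dataclass
class ForwardResult:
    scores: PredictionScores
    O_csa: np.ndarray | None = None
    O_mhsa: np.ndarray | None = None
    caches: dict = field(default_factory=dict)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def contrastive_loss(O_csa: np.ndarray, O_mhsa: np.ndarray) -> float:
    """Mean squared discrepancy between the two branch outputs (N x D)."""
    if O_csa.shape != O_mhsa.shape:
        raise ValueError(f"shape mismatch {O_csa.shape} vs {O_mhsa.shape}")
    return float(np.mean((O_csa - O_mhsa) ** 2))


def main_loss(Y_tilde: float, Y: int) -> float:
    """Binary cross-entropy of the repertoire probability; probabilities are
    clamped to [EPS, 1-EPS] so the loss stays finite at saturation."""
    if Y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {Y}")
    p = min(max(Y_tilde, EPS), 1.0 - EPS)
    return float(-(Y * np.log(p) + (1 - Y) * np.log(1.0 - p)))


def total_loss(L_M: float, L_C: float, lam: float = 1.0) -> float:
    """Combined training objective L = L_M + lambda * L_C."""
    if not (np.isfinite(L_M) and np.isfinite(L_C)):
        raise ValueError(f"non-finite loss terms: L_M={L_M}, L_C={L_C}")
    return float(L_M + lam * L_C)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MILModel:
    """The end-to-end repertoire classifier; parameters in one flat dict."""

    def __init__(self, cfg: ModelConfig, params: dict[str, np.ndarray],
                 trained: bool = False):
        self.cfg = cfg
        self.params = params
        self.trained = trained

    # -- construction -----------------------------------------------------

    @classmethod
    def init(cls, cfg: ModelConfig, rng: np.random.Generator | int) -> "MILModel":
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        feat_cfg = cfg.feature_config()
        feat_cfg.validate()
        params = init_conv_params(feat_cfg, rng)
        att = init_attention_params(cfg.d_feat, cfg.d_proj, cfg.h, rng)
        for name in ("Wq", "bq", "Wk", "bk", "Wv", "bv", "Wa", "ba"):
            params["att_" + name] = getattr(att, name)
        limit = np.sqrt(6.0 / (cfg.d_feat + 1))
        params["dec_W"] = rng.uniform(-limit, limit, size=cfg.d_feat)
        params["dec_b"] = np.zeros(1)
        return cls(cfg, params)

    def attention_params(self) -> AttentionParams:
        p = self.params
        return AttentionParams(
            Wq=p["att_Wq"], bq=p["att_bq"], Wk=p["att_Wk"], bk=p["att_bk"],
            Wv=p["att_Wv"], bv=p["att_bv"], Wa=p["att_Wa"], ba=p["att_ba"],
            h=self.cfg.h,
        )

    # -- forward ----------------------------------------------------------

    def forward_from_features(
        self,
        X: np.ndarray,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
        need_dense: bool | None = None,
    ) -> ForwardResult:
        """Attention + decision on a precomputed feature matrix.

        In train mode row dropout is applied and the dense branch is computed
        for the contrastive loss; in eval mode the forward pass is a pure
        function of (X, params) and the dense branch is skipped unless
        requested.
        """
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty repertoire")
        cfg = self.cfg
        caches: dict = {}

        Xd = X
        if mode == "train" and cfg.dropout > 0:
            if rng is None:
                raise ValueError("train-mode forward needs an rng for dropout")
            keep = rng.random(X.shape) >= cfg.dropout
            drop_mask = keep.astype(float) / (1.0 - cfg.dropout)
            Xd = X * drop_mask
            caches["drop_mask"] = drop_mask
        caches["Xd"] = Xd

        att = self.attention_params()
        O_csa = O_mhsa = None
        if cfg.variant == "no_attention":
            O_dec = Xd
        else:
            if cfg.variant == "dense_only":
                O_dec, caches["dense"] = attention_forward(Xd, att, k=None)
                O_mhsa = O_dec
            else:
                k = cfg.k_for(n)
                O_csa, caches["sparse"] = attention_forward(Xd, att, k=k)
                O_dec = O_csa
                if need_dense is None:
                    need_dense = mode == "train" and cfg.variant == "full"
                if need_dense:
                    O_mhsa, caches["dense"] = attention_forward(Xd, att, k=None)

        t = O_dec @ self.params["dec_W"] + self.params["dec_b"][0]
        y = sigmoid(t)
        Y = float(np.mean(y))
        scores = PredictionScores(y_tilde=y, Y_tilde=Y,
                                  label_pred=int(Y > 0.5))
        caches["O_dec"] = O_dec
        caches["y"] = y
        return ForwardResult(scores=scores, O_csa=O_csa, O_mhsa=O_mhsa,
                             caches=caches)

    def forward(
        self,
        encoded: np.ndarray,
        lengths: np.ndarray,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
    ) -> ForwardResult:
        """Full forward pass from encoded sequences; feature caches retained."""
        feat_cfg = self.cfg.feature_config()
        feat_cache = _forward_features(encoded, lengths, feat_cfg, self.params)
        res = self.forward_from_features(feat_cache["X"], mode=mode, rng=rng)
        res.caches["features"] = feat_cache
        return res

    def predict_repertoire(
        self, rep: Repertoire, aafm: np.ndarray | None = None
    ) -> PredictionScores:
        """Convenience eval-mode prediction for one already-filtered repertoire."""
        if aafm is None:
            aafm = default_aa_factors(self.cfg.d_in)
        encoded, lengths = encode_repertoire(rep, aafm, self.cfg.l_max)
        return self.forward(encoded, lengths, mode="eval").scores

    # -- training step ----------------------------------------------------

    def loss_and_grads(
        self,
        encoded: np.ndarray,
        lengths: np.ndarray,
        label: int,
        rng: np.random.Generator,
    ) -> tuple[dict, dict[str, np.ndarray]]:
        """One bag's losses and analytic parameter gradients (train mode)."""
        cfg = self.cfg
        res = self.forward(encoded, lengths, mode="train", rng=rng)
        n = encoded.shape[0]
        y, Y = res.caches["y"], res.scores.Y_tilde
        L_M = main_loss(Y, label)
        L_C = 0.0
        if cfg.variant == "full" and res.O_mhsa is not None:
            L_C = contrastive_loss(res.O_csa, res.O_mhsa)
        L = total_loss(L_M, L_C, cfg.lam)

        grads: dict[str, np.ndarray] = {}
        att = self.attention_params()

        # decision layer backward
        p = min(max(Y, EPS), 1.0 - EPS)
        dY = (p - label) / (p * (1.0 - p))
        dt = dY * y * (1.0 - y) / n
        O_dec = res.caches["O_dec"]
        grads["dec_W"] = O_dec.T @ dt
        grads["dec_b"] = np.array([dt.sum()])
        dO_dec = np.outer(dt, self.params["dec_W"])

        dXd = np.zeros_like(res.caches["Xd"])
        if cfg.variant == "no_attention":
            dXd += dO_dec
        else:
            d = O_dec.shape[1]
            if cfg.variant == "full" and res.O_mhsa is not None:
                diff = res.O_csa - res.O_mhsa
                gC = cfg.lam * 2.0 / (n * d) * diff
                dXd += attention_backward(dO_dec + gC, res.caches["sparse"],
                                          att, grads)
                dXd += attention_backward(-gC, res.caches["dense"], att, grads)
            elif cfg.variant == "dense_only":
                dXd += attention_backward(dO_dec, res.caches["dense"], att, grads)
            else:  # no_contrastive: sparse branch only
                dXd += attention_backward(dO_dec, res.caches["sparse"], att, grads)

        if "drop_mask" in res.caches:
            dX = dXd * res.caches["drop_mask"]
        else:
            dX = dXd
        _backward_features(dX, res.caches["features"], cfg.feature_config(),
                           self.params, grads)

        losses = {"L": L, "L_M": L_M, "L_C": L_C, "Y_tilde": Y}
        if not np.isfinite(L):
            raise RuntimeError(f"non-finite training loss: {losses}")
        return losses, grads

    # -- interpretation helpers -------------------------------------------

    def score_tcrs(
        self, rep: Repertoire, aafm: np.ndarray | None = None
    ) -> tuple[list[tuple[str, float]], PredictionScores]:
        """Rank the repertoire's TCRs by descending cancer-association score.

        Scores are only meaningful when the repertoire itself is predicted
        cancerous; the repertoire-level prediction is returned alongside so
        callers can gate on it.
        """
        scores = self.predict_repertoire(rep, aafm)
        order = np.argsort(-scores.y_tilde, kind="stable")
        ranked = [(rep.tcrs[i].cdr3, float(scores.y_tilde[i])) for i in order]
        return ranked, scores

    # -- persistence ------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Serialize config + all parameters to a JSON checkpoint."""
        payload = {
            "format": "tcrmil-checkpoint",
            "version": 1,
            "config": asdict(self.cfg),
            "trained": self.trained,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "MILModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "tcrmil-checkpoint":
            raise ValueError(f"{path} is not a tcrmil checkpoint")
        cfg_d = payload["config"]
        cfg_d["filter_widths"] = tuple(cfg_d["filter_widths"])
        cfg = ModelConfig(**cfg_d)
        params = {k: np.array(v, dtype=float)
                  for k, v in payload["params"].items()}
        return cls(cfg, params, trained=payload.get("trained", False))

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}
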