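"""Training loop, nested cross-validation and evaluation metrics.

Training minimizes the combined loss with Adam at learning rate 0.001, one
repertoire (bag) per step, shuffled each epoch with a seeded generator.
Early stopping monitors validation AUC with a patience window; the returned
parameters are those of the best-validation epoch.  Model selection follows
the K-K'-fold nested cross-validation protocol (default 5-4): the outer K
folds provide untouched test sets, and within each outer fold a K'-fold
inner cross-validation picks the final model by validation AUC.

Metrics: accuracy, sensitivity, specificity and the Matthews correlation
coefficient from the confusion counts, plus rank-based ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from .model import MILModel, ModelConfig


@dataclass
class TrainConfig:
    """Optimization and protocol hyperparameters (reference defaults:
    N=100, lr=0.001, 500 epochs, D'=10, h=1, k_r=0.05, dropout 0.4)."""

    learning_rate: float = 0.001
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0
    n_top: int = 100
    d_proj: int = 10
    h: int = 1
    k_r: float = 0.05
    dropout: float = 0.4
    lam: float = 1.0
    variant: str = "full"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            n_top=self.n_top, d_proj=self.d_proj, h=self.h, k_r=self.k_r,
            dropout=self.dropout, lam=self.lam, variant=self.variant,
        )


@dataclass
class FoldSplit:
    """One (outer, inner) cell of the nested cross-validation."""

    outer_fold: int
    inner_fold: int
    train_ids: list
    val_ids: list
    test_ids: list

    def check_disjoint(self) -> None:
        tr, va, te = map(set, (self.train_ids, self.val_ids, self.test_ids))
        if tr & va or tr & te or va & te:
            raise AssertionError("overlapping nested-CV splits")


@dataclass
class MetricsReport:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    SEN: float
    SPE: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_metrics(y_true, y_pred) -> MetricsReport:
    """ACC/SEN/SPE/MCC from binary labels and hard predictions.

    MCC is defined as 0 when its denominator vanishes (a degenerate table).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    spe = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(TP=tp, TN=tn, FP=fp, FN=fn, ACC=acc, SEN=sen,
                         SPE=spe, MCC=float(mcc))


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties count one half.

    Raises on single-class input, where the AUC is undefined.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Nested cross-validation splits
# ---------------------------------------------------------------------------

def _stratified_folds(ids: np.ndarray, labels: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Split ids into k label-stratified folds after a seeded shuffle."""
    folds: list[list] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        members = ids[labels == cls]
        if len(members) < k:
            raise ValueError(
                f"class {cls} has {len(members)} samples, fewer than K={k}")
        members = members[rng.permutation(len(members))]
        for i, m in enumerate(members):
            folds[i % k].append(m)
    return [np.array(f) for f in folds]


def nested_cv_split(sample_ids, labels, K: int = 5, K_inner: int = 4,
                    seed: int = 0) -> list[FoldSplit]:
    """All K*K' (train, val, test) triples of the nested protocol.

    Outer folds partition the cohort into K test sets; within each outer
    fold the remaining samples are re-partitioned into K' validation folds.
    Both levels are stratified by label and deterministic given the seed.
    """
    ids = np.asarray(sample_ids)
    labels = np.asarray(labels, dtype=int)
    label_of = dict(zip(ids.tolist(), labels.tolist()))
    rng = np.random.default_rng(seed)
    outer = _stratified_folds(ids, labels, K, rng)
    splits = []
    for ko in range(K):
        test = outer[ko]
        rest = np.concatenate([outer[j] for j in range(K) if j != ko])
        rest_labels = np.array([label_of[s] for s in rest.tolist()])
        inner = _stratified_folds(rest, rest_labels, K_inner, rng)
        for ki in range(K_inner):
            val = inner[ki]
            train = np.concatenate(
                [inner[j] for j in range(K_inner) if j != ki])
            fs = FoldSplit(outer_fold=ko + 1, inner_fold=ki + 1,
                           train_ids=train.tolist(), val_ids=val.tolist(),
                           test_ids=test.tolist())
            fs.check_disjoint()
            splits.append(fs)
    return splits


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Minimal Adam optimizer over a flat parameter dict; in-place updates."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _eval_scores(model: MILModel, data: dict, ids) -> np.ndarray:
    return np.array([
        model.forward(data[s]["encoded"], data[s]["lengths"]).scores.Y_tilde
        for s in ids
    ])


def train_model(
    data: dict,
    labels: dict,
    cfg: TrainConfig,
    split: FoldSplit,
) -> tuple[MILModel, dict]:
    """Train on ``split.train_ids`` with early stopping on validation AUC.

    ``data`` maps sample_id -> {"encoded": (n, l_max, d), "lengths": (n,)};
    ``labels`` maps sample_id -> {0, 1}.  Returns the model restored to its
    best-validation-epoch parameters, plus a per-epoch history.
    """
    split.check_disjoint()
    rng = np.random.default_rng(cfg.seed)
    model = MILModel.init(cfg.model_config(), rng)
    opt = Adam(model.params, cfg.learning_rate, cfg.adam_beta1,
               cfg.adam_beta2, cfg.adam_eps)

    train_ids = list(split.train_ids)
    val_labels = np.array([labels[s] for s in split.val_ids], dtype=int)
    best_auc = -np.inf
    best_params = model.copy_params()
    best_epoch = 0
    history = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_ids))
        ep_loss = 0.0
        for i in order:
            s = train_ids[i]
            losses, grads = model.loss_and_grads(
                data[s]["encoded"], data[s]["lengths"], labels[s], rng)
            opt.step(grads)
            ep_loss += losses["L"]
        val_scores = _eval_scores(model, data, split.val_ids)
        val_auc = auc(val_scores, val_labels)
        history.append({"epoch": epoch, "train_loss": ep_loss / len(train_ids),
                        "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc = val_auc
            best_params = model.copy_params()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.params = best_params
    model.trained = True
    return model, {"history": history, "best_epoch": best_epoch,
                   "best_val_auc": float(best_auc)}


def select_final_model(inner_results: list[tuple[MILModel, float]]) -> MILModel:
    """Pick the inner model with highest validation AUC; ties go to the
    lowest inner-fold id (list order)."""
    if not inner_results:
        raise ValueError("no inner models to select from")
    best = max(range(len(inner_results)),
               key=lambda i: (inner_results[i][1], -i))
    return inner_results[best][0]


def evaluate_model(model: MILModel, data: dict, labels: dict, ids) -> MetricsReport:
    """Hard-label confusion metrics plus AUC on the given sample ids."""
    scores = _eval_scores(model, data, ids)
    y_true = np.array([labels[s] for s in ids], dtype=int)
    y_pred = (scores > 0.5).astype(int)
    rep = confusion_metrics(y_true, y_pred)
    rep.AUC = auc(scores, y_true) if len(np.unique(y_true)) > 1 else None
    return rep


@dataclass
class NestedCVResult:
    fold_metrics: list[MetricsReport]
    final_models: list[MILModel]
    splits: list[FoldSplit]
    inner_val_aucs: list[list[float]] = field(default_factory=list)

    def summary(self) -> dict:
        """Mean +/- sd over outer folds for each metric."""
        out = {}
        for name in ("ACC", "SEN", "SPE", "MCC", "AUC"):
            vals = [getattr(m, name) for m in self.fold_metrics
                    if getattr(m, name) is not None]
            out[name] = (float(np.mean(vals)), float(np.std(vals)))
        return out


def run_nested_cv(
    data: dict,
    labels: dict,
    cfg: TrainConfig,
    K: int = 5,
    K_inner: int = 4,
) -> NestedCVResult:
    """Full K-K' nested cross-validation: train K*K' inner models, select one
    final model per outer fold by validation AUC, and evaluate it on that
    fold's untouched test set."""
    ids = sorted(data.keys())
    label_arr = np.array([labels[s] for s in ids], dtype=int)
    splits = nested_cv_split(ids, label_arr, K=K, K_inner=K_inner,
                             seed=cfg.seed)
    fold_metrics, final_models, all_val_aucs = [], [], []
    for ko in range(1, K + 1):
        cell = [s for s in splits if s.outer_fold == ko]
        inner = []
        for s in cell:
            model, info = train_model(data, labels, cfg, s)
            inner.append((model, info["best_val_auc"]))
        final = select_final_model(inner)
        metrics = evaluate_model(final, data, labels, cell[0].test_ids)
        fold_metrics.append(metrics)
        final_models.append(final)
        all_val_aucs.append([a for _, a in inner])
    return NestedCVResult(fold_metrics=fold_metrics, final_models=final_models,
                          splits=splits, inner_val_aucs=all_val_aucs)
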