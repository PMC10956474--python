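"""Motif-level interpretation of a trained repertoire classifier.

For each TCR, every convolutional filter localizes one candidate motif (the
subsequence under its 1-max-pooled window).  The filter's *motif score* is a
first-order (gradient x input) attribution of that feature to the TCR's
decision logit, squashed through a sigmoid so that zero contribution maps to
0.5; motifs with score strictly above 0.5 are called *positive*.  Per-residue
weight profiles aggregate positive-motif coverage over a CDR3, and a small
enrichment helper turns occurrence counts of a motif in two TCR sets into
the percentages and ratio used for reporting.

The motif-score definition is this package's reconstruction of attribution
"from the trained weights": the exact contribution of feature f to TCR i's
logit along the sparse-attention + decision path, c_f = X[i,f] *
d(logit_i)/d(X[i,f]), computed by the analytic backward pass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .attention import attention_backward
from .model import MILModel, sigmoid
from .preprocess import Repertoire, default_aa_factors, encode_repertoire


@dataclass
class MotifCall:
    """One filter's localized motif on one TCR, with its attribution score."""

    tcr_id: str
    filter_id: int
    start: int
    width: int
    subsequence: str
    motif_score: float


@dataclass
class EnrichmentResult:
    """Occurrence of a motif in two TCR sets, as exact fractions and display
    percentages (one decimal)."""

    count_a: int
    total_a: int
    count_b: int
    total_b: int

    @property
    def frac_a(self) -> float:
        return self.count_a / self.total_a

    @property
    def frac_b(self) -> float:
        return self.count_b / self.total_b

    @property
    def pct_a(self) -> float:
        return round(100.0 * self.frac_a, 1)

    @property
    def pct_b(self) -> float:
        return round(100.0 * self.frac_b, 1)

    @property
    def ratio(self) -> float:
        if self.frac_b == 0:
            return float("nan")
        return self.frac_a / self.frac_b


# ---------------------------------------------------------------------------
# Gradient x input attribution
# ---------------------------------------------------------------------------

def logit_input_gradients(model: MILModel, encoded: np.ndarray,
                          lengths: np.ndarray) -> dict:
    """Eval-mode forward plus, for every TCR i, the exact gradient of its
    decision logit with respect to its own feature row X[i, :].

    Returns X, pool positions, per-TCR logit gradients (n x D) and the
    forward result.  Top-k routing is treated as locally constant, matching
    the training-time gradient.
    """
    res = model.forward(encoded, lengths, mode="eval")
    feat = res.caches["features"]
    X = feat["X"]
    n, d = X.shape
    Wd = model.params["dec_W"]
    att = model.attention_params()
    grad_rows = np.zeros((n, d))
    if model.cfg.variant == "no_attention":
        grad_rows[:] = Wd[None, :]
    else:
        branch = "dense" if model.cfg.variant == "dense_only" else "sparse"
        cache = res.caches[branch]
        for i in range(n):
            dO = np.zeros((n, d))
            dO[i] = Wd
            dX = attention_backward(dO, cache, att, {})
            grad_rows[i] = dX[i]
    return {"X": X, "pool_positions": feat["pos"], "grad_rows": grad_rows,
            "result": res}


def motif_scores(model: MILModel, rep: Repertoire, tcr_index: int,
                 aafm: np.ndarray | None = None) -> list[MotifCall]:
    """All motif calls (one per filter) of one TCR in its repertoire context."""
    calls = repertoire_motif_calls(model, rep, aafm)
    n_f = len(model.cfg.filter_widths)
    return calls[tcr_index * n_f:(tcr_index + 1) * n_f]


def repertoire_motif_calls(model: MILModel, rep: Repertoire,
                           aafm: np.ndarray | None = None) -> list[MotifCall]:
    """Motif calls for every (TCR, filter) pair of one repertoire."""
    if not model.trained:
        raise ValueError("motif scores require a trained model")
    if aafm is None:
        aafm = default_aa_factors(model.cfg.d_in)
    encoded, lengths = encode_repertoire(rep, aafm, model.cfg.l_max)
    info = logit_input_gradients(model, encoded, lengths)
    X, pos, grad = info["X"], info["pool_positions"], info["grad_rows"]
    widths = model.cfg.filter_widths
    calls = []
    for i, tcr in enumerate(rep.tcrs):
        contrib = X[i] * grad[i]
        for f, w in enumerate(widths):
            start = int(pos[i, f])
            calls.append(MotifCall(
                tcr_id=tcr.cdr3, filter_id=f, start=start, width=w,
                subsequence=tcr.cdr3[start:start + w],
                motif_score=float(sigmoid(np.array([contrib[f]]))[0]),
            ))
    return calls


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def positive_motifs(calls: list[MotifCall],
                    threshold: float = 0.5) -> tuple[list[MotifCall], Counter]:
    """Motif calls with score strictly above the threshold, plus a histogram
    of their widths."""
    pos = [c for c in calls if c.motif_score > threshold]
    return pos, Counter(c.width for c in pos)


def aa_weight_profile(cdr3: str, calls: list[MotifCall]) -> np.ndarray:
    """Per-residue weights of one CDR3 from its positive motif calls.

    Each position accumulates (score - 0.5) over the positive motifs covering
    it; the profile is normalized by its maximum (an all-zero profile stays
    zero), so values live in [0, 1] and mark where the model focused.
    """
    weights = np.zeros(len(cdr3))
    for c in calls:
        if c.tcr_id != cdr3 or c.motif_score <= 0.5:
            continue
        weights[c.start:c.start + c.width] += c.motif_score - 0.5
    peak = weights.max()
    if peak > 0:
        weights = weights / peak
    return weights


def motif_enrichment(count_a: int, total_a: int, count_b: int,
                     total_b: int) -> EnrichmentResult:
    """Occurrence percentages of a motif in set A vs set B and their ratio."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie within their totals")
    return EnrichmentResult(count_a, total_a, count_b, total_b)


def high_confidence_tcrs(predictions: list[tuple[str, str, float]],
                         threshold: float = 0.999) -> list[tuple[str, str, float]]:
    """TCRs with score strictly above the threshold, sorted descending.

    ``predictions`` are (sample_id, cdr3, score) triples, normally restricted
    to repertoires the model predicted cancerous — TCR scores carry no
    meaning inside a predicted non-cancerous repertoire.
    """
    hits = [p for p in predictions if p[2] > threshold]
    return sorted(hits, key=lambda p: (-p[2], p[0], p[1]))
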