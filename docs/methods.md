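# Methods

## Problem and model

`tcrmil` classifies T-cell-receptor (TCR) repertoires as cancer-associated
or not, and scores the individual receptors inside a repertoire. The setting
is multi-instance learning (MIL): the label attaches to the *bag* (the
repertoire, a set of CDR3β amino-acid sequences with clone abundances), not
to its instances, and in a cancerous repertoire only a sparse minority of
TCRs is expected to be tumor-reactive.

The pipeline, in the order it runs:

1. **Preprocessing.** Each clonotype table is cleaned with five sequential
   rules — (I) length outside [10, 24]; (II) characters outside the 20
   standard amino-acid letters; (III) not starting with `C` or not ending
   with `F`; (IV) an unresolved V-gene call, applied only when the input
   carries a V column; (V) membership in an optional background-CDR3
   blacklist. Removals are attributed to the first violated rule, so the
   per-rule counts of a `FilterReport` are well defined, and the bounds of
   rule I are inclusive on the keep side ([10, 24] survives). The N = 100
   most abundant survivors are kept (ties broken lexicographically, then by
   file order, for bit-reproducibility) and each sequence of length *l* is
   embedded into an *l* × 15 matrix via a 20 × 15 amino-acid factor matrix.

2. **Motif features.** 14 convolutional filters of widths 2–8 (two per
   width — covering the 2–7 residue range of reported antigen-binding
   motifs, with one wider size for slack) scan each embedded sequence; ReLU
   then 1-max pooling over the valid (unpadded) windows reduces each filter
   map to a scalar. A repertoire becomes an N × 14 feature matrix X, and the
   pooled argmax positions are retained to map filters back to subsequences.

3. **Attention.** X is projected to queries/keys/values (D′ = 10, h = 1
   head by default). Two branches share every parameter, including the
   output projection back to 14 dimensions:
   * dense multi-head self-attention, `softmax(Q Kᵀ/√d_head) V`;
   * content-based sparse self-attention: the affinity graph `A = Q Kᵀ` is
     pruned per row to the top k = max(1, ⌊k_r·n⌋) entries (k_r = 0.05), and
     each TCR attends only to its k most related TCRs. Sparse attention is
     computed as dense attention with non-selected logits at −∞, which is
     algebraically identical to gathering the selected key/value rows, and
     reduces exactly to the dense branch at k = n.

4. **Decision and losses.** Per-TCR scores are
   `ỹ = sigmoid(O^CSA′ W_D + b_D)`; the repertoire probability is their
   mean, with the strict rule Ỹ > 0.5 ⇒ cancerous. Training minimizes
   `L = L_M + λ·L_C` with λ = 1, where L_M is binary cross-entropy on Ỹ
   (clamped to [1e−7, 1−1e−7]) and L_C is the mean squared discrepancy
   between the sparse and dense branch outputs — the self-contrastive
   regularizer that steers dense attention toward the sparse routing.
   Both branches receive gradients; no stop-gradient is used.

All of this is implemented in numpy with analytically derived gradients and
a small Adam optimizer (lr 0.001, β = 0.9/0.999); the top-k routing is
treated as locally constant during differentiation, as is standard for
discrete selection.

## Training protocol

One repertoire per optimizer step, epochs shuffled with a seeded generator;
40% element-wise dropout on X during training only. Early stopping monitors
validation AUC with patience 20 (maximum 500 epochs) and restores the
parameters of the best-validation epoch. Evaluation follows 5-4-fold nested
cross-validation: five outer test folds; within each, a four-fold inner
cross-validation trains four candidates and the one with the highest
validation AUC (ties to the lowest fold id) is evaluated once on the outer
test fold. Folds are stratified by label so both classes appear in every
fold at small cohort sizes. Reported metrics (ACC, SEN, SPE, MCC, AUC) are
averaged over outer folds; MCC is defined as 0 when its denominator
vanishes.

Dropout granularity is element-wise rather than whole-row. Row dropout
zeroes ~40% of instances into identical all-zero rows, whose tied
affinities give the sparse router a degenerate routing channel and, under
the contrastive term, a collapse mode that destroys learning; element-wise
dropout (the conventional reading of a 40% dropout on a feature matrix)
avoids this entirely.

## Amino-acid embedding

The default 20 × 15 factor matrix is a constructed stand-in for published
biochemical factor matrices, which are not redistributed here: each residue
is represented by the first 15 principal components of its BLOSUM62
substitution-score row, sign-fixed and column-standardized, so residues
with similar substitution behaviour lie close in embedding space and the
construction is fully deterministic. Any user-supplied 20 × d matrix is
accepted (`load_aa_factors`), and the unit tests use an injective synthetic
matrix so that no correctness claim depends on any particular embedding.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
the biology of V(D)J recombination. Background sequences start with `C`,
end with `F`, have lengths in [10, 24] (bell-shaped around 15), and draw
interior residues from a field-typical CDR3 composition
(glycine/serine-rich, tryptophan/cysteine/methionine-poor). Positive
repertoires carry exactly round(0.1·n) planted TCRs in which a short motif
(default `NVLT`, a rear-biased substitution that never touches the terminal
residues) replaces part of an otherwise background interior; negatives
carry none. Substitution rather than insertion keeps sequence length
independent of the label, and abundances follow a geometric rank decay
shuffled across TCRs, so neither length nor abundance carries label signal.
Truth annotations live in a separate file from the clonotype tables.

Default study conditions: 40 positive + 40 negative repertoires of 100 TCRs
with a 10% planted minority; the ablation comparison uses a deliberately
harder cohort (20 + 20 repertoires, 5% planted). These sizes keep a full
3-seed nested cross-validation plus a 5-seed ablation comparison at around
twenty minutes on one CPU while leaving the bag task non-trivial.

What passing on these cohorts does and does not show: the planted-motif
construction gives perfectly clean instance labels and a single, exactly
repeated signal subsequence — real repertoires have heterogeneous, fuzzy,
low-frequency signals, sequencing noise, and shared public clones. Recovery
here demonstrates the machinery (filters find the motif, routing groups its
carriers, the bag decision generalizes); it does not certify performance on
patient data.

## Design choices in genuinely open places

* **Attention scaling** — dense logits are scaled by √d_head (the standard
  scaled dot product); the affinity graph used for top-k selection is left
  unscaled, since a positive monotone scale cannot change the selection.
* **Shared parameters across branches** — the contrastive comparison is
  only meaningful if both branches use the same Q/K/V and output
  projection; sharing also forces the k = n equivalence used as an oracle.
* **Multi-head sparse routing** — selection and gathering run per head on
  that head's slice, so the k = n equivalence holds for any head count.
* **Ties** — top-k ties break by ascending index; 1-max pooling takes the
  first argmax; top-N abundance ties break lexicographically. All three
  make runs bit-reproducible.
* **Decision bias** — the decision layer uses a scalar broadcast bias, the
  only reading consistent with an N × 1 output.
* **Bags are not padded** — a repertoire with n < 100 TCRs is used as-is
  and k is recomputed from its actual size.
* **Motif score** — defined here (the underlying method leaves it open) as
  a first-order gradient × input attribution: the contribution of feature f
  to TCR i's logit through the sparse-attention + decision path, squashed by
  a sigmoid so zero contribution maps to 0.5, matching the strict > 0.5
  positive-motif convention. Residue weights sum (score − 0.5) over the
  positive motifs covering a position and normalize by the maximum.
* **Early-stopping monitor** — validation AUC with patience 20.
  Alternatives explored (validation loss, AUC with loss tie-break, the
  combined objective) systematically restored later checkpoints that
  degraded planted-TCR ranking and were rejected.

## Known limitations

* With mean pooling, positive-bag classification forces background-TCR
  scores toward the decision region, compressing the score range available
  for instance discrimination; the polarity of instance scores inside
  positive bags is only weakly identified by the bag objective, and content
  routing can channel bag-level evidence into background instances. The
  repertoire-level AUC is robust; the planted-vs-background ranking AUC is
  noticeably noisier across folds and seeds.
* Dot-product affinity lets large-norm keys attract every query; with
  extreme embedding outliers planted in every signal TCR this can invert
  instance polarity wholesale (observed with artificial tryptophan-rich
  motifs, a reason the default planted motif is composition-typical).
* Stacked/autoencoder feature extraction and α-chain modelling are out of
  scope, as are reconstruction of TCRs from raw reads and external
  database cross-referencing beyond the counts-in/percentages-out
  enrichment helper.
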