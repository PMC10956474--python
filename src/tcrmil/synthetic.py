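"""Synthetic labeled cohorts with planted signal motifs.

The generator emulates the statistical structure the classifier assumes:
every repertoire is a bag of background CDR3-like sequences (start 'C', end
'F', lengths 10-24, interior drawn from a background amino-acid frequency
table), and in *positive* repertoires a sparse minority of TCRs carry a
short planted motif (default 10%, one motif of length 4) substituted into
the middle/rear interior of an otherwise background sequence.  Substitution
rather than insertion keeps the length distribution identical between
classes, so labels cannot be predicted from sequence length.  Clone
abundances follow a geometric rank decay, shuffled across TCRs so abundance
carries no label signal either.

Truth annotations (which TCRs are planted, with which motif) are written to
a separate file so the training pipeline can never consume them by accident.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .preprocess import AA_ALPHABET, Repertoire, RawTCR


#: Field-typical amino-acid usage of CDR3 interiors (glycine/serine-rich,
#: tryptophan/cysteine/methionine-poor); the default background composition.
#: A uniform table can be supplied instead to stress-test.
CDR3_BACKGROUND_FREQS = {
    "G": 0.12, "S": 0.11, "E": 0.07, "T": 0.07, "L": 0.07, "A": 0.06,
    "Q": 0.06, "R": 0.06, "N": 0.05, "Y": 0.05, "D": 0.05, "P": 0.04,
    "F": 0.04, "V": 0.04, "I": 0.03, "K": 0.03, "H": 0.02, "W": 0.02,
    "C": 0.01, "M": 0.01,
}


def _default_length_dist() -> dict[int, float]:
    """Bell-shaped CDR3 length distribution over [10, 24], mode 15."""
    lengths = np.arange(10, 25)
    w = np.exp(-((lengths - 15.0) ** 2) / (2 * 2.5 ** 2))
    w /= w.sum()
    return dict(zip(lengths.tolist(), w.tolist()))


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters.

    Defaults define the package's reference study conditions: 40 + 40
    repertoires of 100 TCRs, 10% of TCRs in positive repertoires carrying
    the planted motif (the signal minority stays well under 20% of the bag),
    motif planted with a rear-position bias.
    """

    n_pos: int = 40
    n_neg: int = 40
    n_tcr: int = 100
    planted_fraction: float = 0.1
    motif_set: tuple = ("NVLT",)
    motif_position: str = "rear"  # rear | middle | uniform
    length_distribution: dict = field(default_factory=_default_length_dist)
    #: interior letter frequencies; None means uniform over the 20 letters
    background_freqs: dict | None = field(
        default_factory=lambda: dict(CDR3_BACKGROUND_FREQS))
    abundance_top: float = 1000.0
    abundance_decay: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.planted_fraction <= 0.2):
            raise ValueError("planted_fraction must lie in (0, 0.2]")
        for m in self.motif_set:
            if any(c not in AA_ALPHABET for c in m):
                raise ValueError(f"motif {m!r} uses non-standard letters")
            if not (2 <= len(m) <= 7):
                raise ValueError(f"motif {m!r} length outside [2, 7]")
        if self.motif_position not in ("rear", "middle", "uniform"):
            raise ValueError(f"unknown position bias {self.motif_position!r}")

    @property
    def n_planted(self) -> int:
        return int(round(self.planted_fraction * self.n_tcr))


# ---------------------------------------------------------------------------
# Primitive samplers
# ---------------------------------------------------------------------------

def sample_background_cdr3(length_distribution: dict[int, float],
                           rng: np.random.Generator,
                           background_freqs: dict | None = None) -> str:
    """One background sequence: 'C' + random interior + 'F'.

    Satisfies filter rules I-III by construction.
    """
    lengths = np.array(sorted(length_distribution))
    probs = np.array([length_distribution[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    l = int(rng.choice(lengths, p=probs))
    letters = np.array(list(AA_ALPHABET))
    if background_freqs is None:
        p = None
    else:
        p = np.array([background_freqs.get(a, 0.0) for a in AA_ALPHABET])
        p = p / p.sum()
    interior = "".join(rng.choice(letters, size=l - 2, p=p))
    return "C" + interior + "F"


def plant_motif(seq: str, motif: str, position_bias: str,
                rng: np.random.Generator) -> tuple[str, int]:
    """Substitute ``motif`` into the interior of ``seq`` at a biased offset.

    The first and last residues are never overwritten and the length is
    unchanged.  Returns the modified sequence and the 0-based offset.
    """
    w = len(motif)
    if w > len(seq) - 2:
        raise ValueError(
            f"motif of length {w} cannot fit the interior of a "
            f"length-{len(seq)} sequence")
    starts = np.arange(1, len(seq) - w)  # keep positions 0 and len-1 intact
    if position_bias == "rear":
        weights = (starts - starts[0] + 1.0) ** 2
    elif position_bias == "middle":
        center = (starts[0] + starts[-1]) / 2.0
        weights = 1.0 / (1.0 + (starts - center) ** 2)
    else:
        weights = np.ones_like(starts, dtype=float)
    weights = weights / weights.sum()
    start = int(rng.choice(starts, p=weights))
    return seq[:start] + motif + seq[start + w:], start


def _abundances(n: int, cfg: SyntheticConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Geometric rank-decay clone sizes, shuffled across TCRs."""
    ranks = np.arange(n)
    a = np.maximum(1, np.round(cfg.abundance_top * cfg.abundance_decay ** ranks))
    return a[rng.permutation(n)]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class PlantedRecord:
    sample_id: str
    tcr_index: int
    cdr3: str
    motif: str
    offset: int


def generate_repertoires(
    cfg: SyntheticConfig,
) -> tuple[list[Repertoire], list[PlantedRecord]]:
    """In-memory cohort: positive then negative repertoires, plus the truth
    table of planted TCRs.  Deterministic for a fixed config/seed."""
    rng = np.random.default_rng(cfg.seed)
    reps: list[Repertoire] = []
    truth: list[PlantedRecord] = []
    for label, count, tag in ((1, cfg.n_pos, "pos"), (0, cfg.n_neg, "neg")):
        for j in range(count):
            sid = f"{tag}_{j + 1:03d}"
            seqs = [sample_background_cdr3(cfg.length_distribution, rng,
                                           cfg.background_freqs)
                    for _ in range(cfg.n_tcr)]
            if label == 1:
                planted_idx = rng.choice(cfg.n_tcr, size=cfg.n_planted,
                                         replace=False)
                for i in sorted(planted_idx.tolist()):
                    motif = cfg.motif_set[int(rng.integers(len(cfg.motif_set)))]
                    seqs[i], off = plant_motif(seqs[i], motif,
                                               cfg.motif_position, rng)
                    truth.append(PlantedRecord(sample_id=sid, tcr_index=i,
                                               cdr3=seqs[i], motif=motif,
                                               offset=off))
            ab = _abundances(cfg.n_tcr, cfg, rng)
            tcrs = [RawTCR(cdr3=s, abundance=float(a))
                    for s, a in zip(seqs, ab)]
            reps.append(Repertoire(sample_id=sid, tcrs=tcrs, label=label))
    return reps, truth


def generate_cohort(cfg: SyntheticConfig, out_dir: str | os.PathLike) -> dict:
    """Write a cohort to disk: one clonotype TSV per repertoire, a manifest
    (sample_id, path, label) and a separate truth table for planted TCRs.

    Returns the paths written.  Output is byte-identical across runs with
    the same config.
    """
    out_dir = os.fspath(out_dir)
    rep_dir = os.path.join(out_dir, "repertoires")
    os.makedirs(rep_dir, exist_ok=True)
    reps, truth = generate_repertoires(cfg)

    manifest_rows = []
    for rep in reps:
        fname = f"{rep.sample_id}.tsv"
        with open(os.path.join(rep_dir, fname), "w") as fh:
            fh.write("junction_aa\tduplicate_count\n")
            for t in rep.tcrs:
                fh.write(f"{t.cdr3}\t{int(t.abundance)}\n")
        manifest_rows.append((rep.sample_id, os.path.join("repertoires", fname),
                              rep.label))

    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("sample_id\tpath\tlabel\n")
        for sid, path, label in manifest_rows:
            fh.write(f"{sid}\t{path}\t{label}\n")

    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("sample_id\ttcr_index\tcdr3\tmotif\toffset\n")
        for r in truth:
            fh.write(f"{r.sample_id}\t{r.tcr_index}\t{r.cdr3}\t{r.motif}\t"
                     f"{r.offset}\n")

    return {"manifest": manifest_path, "truth": truth_path,
            "repertoire_dir": rep_dir, "n_files": len(manifest_rows)}
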