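"""Clonotype-table preprocessing: parsing, filtering, top-N selection, encoding.

A repertoire is one sample's bag of CDR3 beta-chain amino-acid sequences with
clone abundances.  Before feature extraction every repertoire is cleaned with
five sequential filter rules:

  I.   length outside [10, 24];
  II.  characters outside the 20 standard amino-acid letters;
  III. not starting with cysteine ('C') or not ending with phenylalanine ('F');
  IV.  unresolved V-gene call (only when the input carried a V column);
  V.   exact match to a user-supplied background-CDR3 blacklist.

Removals are attributed to the first violated rule, so per-rule counts in a
:class:`FilterReport` are well defined.  The surviving sequences are ranked by
abundance and the top N (default 100) kept, then each sequence is embedded
into an ``l x d`` numeric matrix by a 20 x d amino-acid factor matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical ordering of the 20 standard amino acids used everywhere.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Length bounds of rule I (inclusive keep-range).
MIN_LENGTH = 10
MAX_LENGTH = 24

#: Default number of embedding dimensions per residue.
DEFAULT_D = 15

#: Column-name candidates tried in order when no explicit mapping is given.
CDR3_COLUMNS = ("junction_aa", "aaSeqCDR3", "amino_acid")
ABUNDANCE_COLUMNS = ("duplicate_count", "cloneCount", "frequency")
V_COLUMNS = ("v_call", "allVHitsWithScore")

RULES = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class RawTCR:
    """One clonotype record: CDR3 sequence, abundance, optional V call."""

    cdr3: str
    abundance: float
    v_call: str | None = None

    def __post_init__(self):
        if not self.cdr3:
            raise ValueError("empty CDR3 sequence")
        if self.abundance < 0:
            raise ValueError(f"negative abundance for {self.cdr3!r}")


@dataclass
class Repertoire:
    """One sample's bag of TCRs plus its (possibly unknown) binary label."""

    sample_id: str
    tcrs: list[RawTCR]
    label: int | None = None
    #: whether the source file carried a V-gene column (rule IV applicability)
    has_v: bool = False

    def __len__(self) -> int:
        return len(self.tcrs)

    def sequences(self) -> list[str]:
        return [t.cdr3 for t in self.tcrs]


@dataclass
class FilterReport:
    """Per-rule removal counts; each removal attributed to the first violated rule."""

    n_input: int = 0
    n_removed_by_rule: dict = field(default_factory=lambda: {r: 0 for r in RULES})
    n_kept: int = 0

    def check(self) -> None:
        total = self.n_kept + sum(self.n_removed_by_rule.values())
        if total != self.n_input:
            raise AssertionError("filter report does not balance")


@dataclass
class TCRMatrix:
    """``l x d`` embedding of one CDR3, optionally zero-padded below row l."""

    values: np.ndarray
    valid_length: int

    @property
    def d(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Amino-acid factor matrix
# ---------------------------------------------------------------------------

_DEFAULT_FACTORS: np.ndarray | None = None


def default_aa_factors(d: int = DEFAULT_D) -> np.ndarray:
    """Deterministic 20 x d amino-acid factor matrix.

    Synthetic stand-in for published biochemical factor matrices (which are
    not redistributed here): each amino acid is represented by the first *d*
    principal components of its BLOSUM62 substitution-score row, so residues
    with similar substitution behaviour get nearby embeddings.  Columns are
    standardized; signs are fixed so the construction is fully deterministic.
    Any user-supplied 20 x d matrix can be used instead via
    :func:`load_aa_factors`.
    """
    global _DEFAULT_FACTORS
    if _DEFAULT_FACTORS is not None and _DEFAULT_FACTORS.shape[1] == d:
        return _DEFAULT_FACTORS
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    s = np.array(
        [[blosum[a][b] for b in AA_ALPHABET] for a in AA_ALPHABET], dtype=float
    )
    s = s - s.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(s, full_matrices=False)
    scores = u[:, :d] * sv[:d]
    # fix sign per component: largest-|.| entry made positive
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    # standardize columns (zero mean, unit variance where non-degenerate)
    scores -= scores.mean(axis=0, keepdims=True)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    scores /= sd
    if d == DEFAULT_D:
        _DEFAULT_FACTORS = scores
    return scores


def load_aa_factors(path: str | os.PathLike) -> np.ndarray:
    """Load a user 20 x d factor matrix from a TSV with amino-acid row index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [a for a in AA_ALPHABET if a not in df.index]
    if missing:
        raise ValueError(f"factor matrix lacks rows for amino acids {missing}")
    mat = df.loc[list(AA_ALPHABET)].to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[0] != 20:
        raise ValueError(f"factor matrix must be 20 x d, got {mat.shape}")
    return mat


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _resolve_column(df: pd.DataFrame, override: str | None, candidates) -> str | None:
    if override is not None:
        if override not in df.columns:
            raise ValueError(f"configured column {override!r} not in file columns "
                             f"{list(df.columns)}")
        return override
    for c in candidates:
        if c in df.columns:
            return c
    return None


def read_repertoire_file(
    path: str | os.PathLike,
    column_map: dict | None = None,
    sample_id: str | None = None,
    label: int | None = None,
) -> Repertoire:
    """Read one tab-separated clonotype file into a :class:`Repertoire`.

    Recognizes AIRR-style column names by default (``junction_aa`` /
    ``duplicate_count`` / ``v_call``) plus common MiXCR/immunoSEQ dialects;
    override with ``column_map={'cdr3': ..., 'abundance': ..., 'v': ...}``.
    Row order of the file is preserved.
    """
    column_map = column_map or {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    cdr3_col = _resolve_column(df, column_map.get("cdr3"), CDR3_COLUMNS)
    if cdr3_col is None:
        raise ValueError(
            f"{path}: no CDR3 column found; tried {CDR3_COLUMNS}; "
            f"file has {list(df.columns)}"
        )
    ab_col = _resolve_column(df, column_map.get("abundance"), ABUNDANCE_COLUMNS)
    v_col = _resolve_column(df, column_map.get("v"), V_COLUMNS)

    tcrs = []
    for _, row in df.iterrows():
        seq = row[cdr3_col]
        if not isinstance(seq, str) or not seq:
            continue
        ab = 1.0 if ab_col is None else float(row[ab_col])
        v = None
        if v_col is not None:
            v = row[v_col]
            v = None if (not isinstance(v, str)) else v
        tcrs.append(RawTCR(cdr3=seq.strip(), abundance=ab, v_call=v))
    sid = sample_id if sample_id is not None else os.path.splitext(
        os.path.basename(os.fspath(path)))[0]
    return Repertoire(sample_id=sid, tcrs=tcrs, label=label, has_v=v_col is not None)


def read_blacklist(path: str | os.PathLike) -> set[str]:
    """Read a background-CDR3 blacklist: one sequence per line, '#' comments."""
    seqs: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                seqs.add(line)
    return seqs


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest (TSV: sample_id, path, label); paths resolved
    relative to the manifest's directory."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "path": str})
    for col in ("sample_id", "path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    df["path"] = [p if os.path.isabs(p) else os.path.join(base, p)
                  for p in df["path"]]
    df["label"] = df["label"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _violated_rule(t: RawTCR, has_v: bool, blacklist: set[str] | None) -> str | None:
    seq = t.cdr3
    if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
        return "I"
    if any(c not in AA_INDEX for c in seq):
        return "II"
    if not (seq.startswith("C") and seq.endswith("F")):
        return "III"
    if has_v:
        v = t.v_call
        if v is None or v.strip() == "" or v.strip().lower() == "unresolved" \
                or "*" in v:
            return "IV"
    if blacklist and seq in blacklist:
        return "V"
    return None


def filter_sequences(
    rep: Repertoire, blacklist: set[str] | None = None
) -> tuple[Repertoire, FilterReport]:
    """Apply filter rules I-V; removals attributed to the first violated rule.

    Rule IV is skipped entirely when the source file had no V column; rule V
    is skipped when no blacklist is supplied.
    """
    report = FilterReport(n_input=len(rep.tcrs))
    kept = []
    for t in rep.tcrs:
        rule = _violated_rule(t, rep.has_v, blacklist)
        if rule is None:
            kept.append(t)
        else:
            report.n_removed_by_rule[rule] += 1
    report.n_kept = len(kept)
    report.check()
    return replace(rep, tcrs=kept), report


def select_top_n(rep: Repertoire, n: int) -> Repertoire:
    """Keep the n most abundant TCRs, sorted by descending abundance.

    Ties are broken by lexicographic CDR3 order, then original file order,
    making the selection bit-reproducible.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    order = sorted(
        range(len(rep.tcrs)),
        key=lambda i: (-rep.tcrs[i].abundance, rep.tcrs[i].cdr3, i),
    )
    return replace(rep, tcrs=[rep.tcrs[i] for i in order[:n]])


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_sequence(cdr3: str, aafm: np.ndarray) -> TCRMatrix:
    """Embed one CDR3 into an ``l x d`` matrix: row i is the factor vector of
    residue i."""
    try:
        idx = [AA_INDEX[c] for c in cdr3]
    except KeyError as e:
        raise ValueError(f"non-standard amino acid {e.args[0]!r} in {cdr3!r}") from e
    return TCRMatrix(values=aafm[idx].copy(), valid_length=len(cdr3))


def pad_to_length(tm: TCRMatrix, l_max: int = MAX_LENGTH) -> TCRMatrix:
    """Zero-pad below the valid rows up to ``l_max``; valid_length is kept for
    masking so padded rows never enter a convolution window."""
    l = tm.valid_length
    if l > l_max:
        raise ValueError(f"sequence length {l} exceeds L_max={l_max}")
    if tm.values.shape[0] == l_max:
        return tm
    out = np.zeros((l_max, tm.values.shape[1]), dtype=tm.values.dtype)
    out[:l] = tm.values[:l]
    return TCRMatrix(values=out, valid_length=l)


def encode_repertoire(
    rep: Repertoire, aafm: np.ndarray | None = None, l_max: int = MAX_LENGTH
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a filtered repertoire into a padded ``(n, l_max, d)`` array plus
    a length vector."""
    if aafm is None:
        aafm = default_aa_factors()
    mats = [pad_to_length(encode_sequence(t.cdr3, aafm), l_max) for t in rep.tcrs]
    enc = np.stack([m.values for m in mats]) if mats else \
        np.zeros((0, l_max, aafm.shape[1]))
    lengths = np.array([m.valid_length for m in mats], dtype=int)
    return enc, lengths


def load_cohort(
    manifest_path: str | os.PathLike,
    n_top: int = 100,
    blacklist: set[str] | None = None,
    aafm: np.ndarray | None = None,
    l_max: int = MAX_LENGTH,
    column_map: dict | None = None,
) -> tuple[dict, dict, dict]:
    """Read, filter and encode every repertoire named in a manifest.

    Returns ``(data, labels, repertoires)`` where ``data[sample_id]`` holds
    the padded encoding and length vector consumed by the model, and
    ``repertoires`` the filtered :class:`Repertoire` objects.
    """
    if aafm is None:
        aafm = default_aa_factors()
    manifest = read_manifest(manifest_path)
    data, labels, reps = {}, {}, {}
    for row in manifest.itertuples(index=False):
        rep = read_repertoire_file(row.path, column_map=column_map,
                                   sample_id=row.sample_id,
                                   label=int(row.label))
        rep, _ = preprocess_repertoire(rep, n_top=n_top, blacklist=blacklist)
        if len(rep) == 0:
            raise ValueError(f"sample {row.sample_id}: no TCR survived filtering")
        encoded, lengths = encode_repertoire(rep, aafm, l_max)
        data[row.sample_id] = {"encoded": encoded, "lengths": lengths}
        labels[row.sample_id] = int(row.label)
        reps[row.sample_id] = rep
    return data, labels, reps


def preprocess_repertoire(
    rep: Repertoire,
    n_top: int = 100,
    blacklist: set[str] | None = None,
) -> tuple[Repertoire, FilterReport]:
    """Full cleaning pipeline: rules I-V then top-N selection."""
    filtered, report = filter_sequences(rep, blacklist)
    return select_top_n(filtered, n_top), report
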