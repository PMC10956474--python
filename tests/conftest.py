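import numpy as np
import pytest

from tcrmil import SyntheticConfig, generate_repertoires, encode_repertoire
from tcrmil.preprocess import AA_ALPHABET


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def injective_aafm():
    """Deterministic synthetic 20x15 factor matrix with pairwise-distinct
    rows, so sequences are recoverable from their encodings."""
    gen = np.random.default_rng(777)
    m = gen.normal(size=(20, 15))
    # make rows trivially distinguishable: column 0 encodes the row index
    m[:, 0] = np.arange(20)
    return m


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small in-memory synthetic cohort with encodings, for model tests."""
    cfg = SyntheticConfig(n_pos=4, n_neg=4, n_tcr=30, seed=99)
    reps, truth = generate_repertoires(cfg)
    data, labels = {}, {}
    for r in reps:
        enc, lengths = encode_repertoire(r)
        data[r.sample_id] = {"encoded": enc, "lengths": lengths}
        labels[r.sample_id] = r.label
    return {"reps": reps, "truth": truth, "data": data, "labels": labels,
            "config": cfg}


def write_clonotype_tsv(path, rows, columns=("junction_aa", "duplicate_count")):
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture
def clonotype_writer():
    return write_clonotype_tsv


@pytest.fixture(scope="session")
def standard_letters():
    return AA_ALPHABET
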