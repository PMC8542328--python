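import numpy as np
import pytest

from oriseq.sequence_io import LabeledRecord, LabeledSequenceSet


def write_fasta(path, records, wrap=None):
    """records: list of (id, sequence). Plain writer independent of the package."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i:i + wrap] + "\n")
            else:
                fh.write(seq + "\n")
    return str(path)


def make_set(pos_seqs, neg_seqs, species="test"):
    records = tuple(
        [LabeledRecord(f"pos{i}", s, "positive") for i, s in enumerate(pos_seqs)]
        + [LabeledRecord(f"neg{i}", s, "negative") for i, s in enumerate(neg_seqs)]
    )
    return LabeledSequenceSet(records=records, species=species)


def random_set(rng, n_pos, n_neg, length, alphabet="ACGT"):
    bases = list(alphabet)
    draw = lambda: "".join(rng.choice(bases, size=length))
    return make_set([draw() for _ in range(n_pos)],
                    [draw() for _ in range(n_neg)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_set():
    """The two-sequence worked example: positive 'AC', negative 'AA'."""
    return make_set(["AC"], ["AA"])


@pytest.fixture(scope="session")
def depleted_composition():
    """G-depleted background so a planted G-rich motif is a strong signal."""
    return {"A": 0.88 / 3, "C": 0.88 / 3, "T": 0.88 / 3, "G": 0.12}
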