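"""Reading, validating and partitioning labeled DNA sequence sets.

Sequences arrive as two FASTA files per species — one of positive (origin)
sequences, one of negative (background) sequences — and are merged into a
single :class:`LabeledSequenceSet` with the label taken from the file of
origin.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

POSITIVE = "positive"
NEGATIVE = "negative"

_ALPHABET = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised when a FASTA file cannot be parsed or violates the contract."""


@dataclass(frozen=True)
class LabeledRecord:
    """One sequence with its identifier and class label."""

    id: str
    sequence: str
    label: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class LabeledSequenceSet:
    """A two-class collection of DNA sequences for one species.

    Invariants enforced at construction: sequences are uppercase, non-empty
    and drawn from {A,C,G,T,N}; record ids are unique within the set.
    """

    records: tuple[LabeledRecord, ...]
    species: str = ""
    cell_type: str | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        """Binary label vector: 1 for positive, 0 for negative."""
        return np.array([1 if r.label == POSITIVE else 0 for r in self.records],
                        dtype=np.int8)

    def count(self, label: str) -> int:
        return sum(1 for r in self.records if r.label == label)

    @property
    def n_positive(self) -> int:
        return self.count(POSITIVE)

    @property
    def n_negative(self) -> int:
        return self.count(NEGATIVE)

    def subset(self, indices) -> "LabeledSequenceSet":
        recs = tuple(self.records[i] for i in indices)
        return replace(self, records=recs)


def _read_fasta_records(path: str | os.PathLike, label: str) -> list[LabeledRecord]:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FastaFormatError(f"{path}: empty file")
        if first != ">":
            raise FastaFormatError(f"{path}: does not start with a FASTA header")
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        try:
            out.append(LabeledRecord(id=rec.id, sequence=seq, label=label))
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
    if not out:
        raise FastaFormatError(f"{path}: no FASTA records")
    return out


def read_labeled_fasta(
    positive_path: str | os.PathLike,
    negative_path: str | os.PathLike,
    species: str,
    *,
    expected_length: int | None = 300,
    strict_length: bool = False,
    cell_type: str | None = None,
) -> LabeledSequenceSet:
    """Merge a positive and a negative FASTA file into one labeled set.

    The label of each record is determined by its file of origin. Sequences
    are uppercased; characters outside {A,C,G,T,N} are rejected with an
    error naming the offending record.

    ``expected_length`` (default 300) is checked per record: deviations warn
    by default and raise if ``strict_length`` is set. Pass ``None`` to skip
    the check entirely.
    """
    pos = _read_fasta_records(positive_path, POSITIVE)
    neg = _read_fasta_records(negative_path, NEGATIVE)
    overlap = {r.id for r in pos} & {r.id for r in neg}
    if overlap:
        raise FastaFormatError(
            f"record id(s) present in both files: {sorted(overlap)[:5]}"
        )
    records = tuple(pos + neg)
    if expected_length is not None:
        off = [r.id for r in records if len(r.sequence) != expected_length]
        if off:
            msg = (f"{len(off)} record(s) deviate from expected length "
                   f"{expected_length} (first: {off[0]!r})")
            if strict_length:
                raise FastaFormatError(msg)
            warnings.warn(msg, stacklevel=2)
    return LabeledSequenceSet(records=records, species=species, cell_type=cell_type)


def write_labeled_fasta(
    seq_set: LabeledSequenceSet,
    positive_path: str | os.PathLike,
    negative_path: str | os.PathLike,
    *,
    line_width: int = 70,
) -> None:
    """Write the set back out as the two-file FASTA convention."""
    for label, path in ((POSITIVE, positive_path), (NEGATIVE, negative_path)):
        recs = [SeqRecord(Seq(r.sequence), id=r.id, description="")
                for r in seq_set.records if r.label == label]
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
            writer.write_file(recs)


def split_train_test(
    seq_set: LabeledSequenceSet,
    test_fraction: float,
    seed: int,
) -> tuple[LabeledSequenceSet, LabeledSequenceSet]:
    """Stratified, seeded train/test partition.

    Per class, ``floor(n * test_fraction)`` records are held out for the
    test set; the assignment is a seeded permutation, so a fixed seed gives
    an identical partition. Returns ``(train, test)``.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    for label in (POSITIVE, NEGATIVE):
        if seq_set.count(label) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for label in (POSITIVE, NEGATIVE):
        idx = np.array([i for i, r in enumerate(seq_set.records) if r.label == label])
        n_test = int(np.floor(len(idx) * test_fraction))
        chosen = rng.permutation(idx)[:n_test]
        test_idx.extend(int(i) for i in chosen)
    test_mask = np.zeros(len(seq_set), dtype=bool)
    test_mask[test_idx] = True
    train = seq_set.subset(np.flatnonzero(~test_mask))
    test = seq_set.subset(np.flatnonzero(test_mask))
    return train, test


def write_split_manifest(
    path: str | os.PathLike,
    train: LabeledSequenceSet,
    test: LabeledSequenceSet,
) -> None:
    """Record id -> partition as a two-column TSV beside a split."""
    with open(path, "w") as fh:
        fh.write("id\tpartition\n")
        for part, s in (("train", train), ("test", test)):
            for r in s.records:
                fh.write(f"{r.id}\t{part}\n")
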