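"""Sequence-to-vector encoders.

Three encoders are provided:

``tfidf``
    Class-conditional k-mer TF-IDF. Term frequency ``tf_i`` is the i-th
    k-tuple's share of all vocabulary tuple occurrences in the *positive*
    training sequences; ``idf_i = log(|D| / (1 + df_i))`` where ``|D|`` is
    the number of training sequences of both classes and ``df_i`` the
    number containing the tuple. A sequence is encoded as
    ``l_i = tfidf_i * n_i`` with ``n_i`` its own tuple count.

``base_content``
    Four whole-sequence composition scalars: AT-profile, GC-profile,
    GC-skew, AT-skew.

``pseknc``
    Series-correlation pseudo k-tuple composition: normalized k-mer
    frequencies followed by tiered dinucleotide-property correlation
    factors, all sharing one normalizer so the vector sums to 1.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from oriseq.sequence_io import LabeledSequenceSet

_BASES = "ACGT"

# ---------------------------------------------------------------------------
# k-mer vocabulary and counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmerVocabulary:
    """All k-tuples over {A,C,G,T} for k in [k_min, k_max].

    Entries are ordered by ascending k, lexicographic within each k, so the
    index of a tuple is deterministic. For k = 1..6 the vocabulary has
    4 + 16 + 64 + 256 + 1024 + 4096 = 5460 entries.
    """

    k_min: int
    k_max: int
    entries: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.index

    def compatible_with(self, other: "KmerVocabulary") -> bool:
        return (self.k_min, self.k_max, self.entries) == (
            other.k_min, other.k_max, other.entries)


def build_vocabulary(k_min: int, k_max: int, *, max_size: int = 4 ** 12) -> KmerVocabulary:
    """Enumerate the complete k-tuple vocabulary.

    Raises if the requested vocabulary would exceed ``max_size`` entries
    (default 4^12 ≈ 1.7e7), with the size estimate in the message.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    size = sum(4 ** k for k in range(k_min, k_max + 1))
    if size > max_size:
        raise ValueError(
            f"vocabulary for k in [{k_min}, {k_max}] would hold {size} entries, "
            f"exceeding the limit of {max_size}")
    entries = tuple(
        "".join(t)
        for k in range(k_min, k_max + 1)
        for t in itertools.product(_BASES, repeat=k)
    )
    return KmerVocabulary(k_min=k_min, k_max=k_max, entries=entries,
                          index={e: i for i, e in enumerate(entries)})


@dataclass(frozen=True)
class KmerCountVector:
    """Overlapping-window tuple counts for one sequence."""

    counts: np.ndarray
    sequence_id: str = ""


def count_kmers(sequence: str, vocab: KmerVocabulary, *,
                sequence_id: str = "") -> KmerCountVector:
    """Count every vocabulary tuple with overlapping windows.

    Windows containing 'N' contribute to no entry. A sequence shorter than
    ``k_min`` yields an all-zero vector.
    """
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    counts = np.zeros(len(vocab), dtype=np.int64)
    L = len(sequence)
    for k in range(vocab.k_min, vocab.k_max + 1):
        for start in range(L - k + 1):
            window = sequence[start:start + k]
            idx = vocab.index.get(window)
            if idx is not None:  # windows with N are absent from the index
                counts[idx] += 1
    return KmerCountVector(counts=counts, sequence_id=sequence_id)


def count_matrix(seq_set: LabeledSequenceSet, vocab: KmerVocabulary) -> np.ndarray:
    """Stack per-sequence count vectors into an (n, |vocab|) array."""
    return np.array([count_kmers(r.sequence, vocab, sequence_id=r.id).counts
                     for r in seq_set.records], dtype=np.int64)


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TfIdfModel:
    """Frozen TF-IDF statistics fitted on a training set.

    ``tf`` sums to 1 over the vocabulary; ``tfidf = tf * idf`` elementwise.
    ``idf`` may be negative for tuples present in every training sequence —
    the formula is kept verbatim rather than clamped.
    """

    tf: np.ndarray
    idf: np.ndarray
    tfidf: np.ndarray
    n_documents: int
    doc_frequency: np.ndarray
    k_min: int
    k_max: int
    log_base: float | None = None  # None = natural log

    def check_vocab(self, vocab: KmerVocabulary) -> None:
        if (vocab.k_min, vocab.k_max, len(vocab)) != (
                self.k_min, self.k_max, len(self.tf)):
            raise ValueError(
                "vocabulary mismatch: model fitted for "
                f"k in [{self.k_min}, {self.k_max}] ({len(self.tf)} tuples), "
                f"got k in [{vocab.k_min}, {vocab.k_max}] ({len(vocab)} tuples)")


def fit_tfidf(train: LabeledSequenceSet, vocab: KmerVocabulary, *,
              log_base: float | None = None) -> TfIdfModel:
    """Fit TF-IDF on a training set.

    ``tf_i`` = count of tuple i across positive training sequences, divided
    by the total count of all vocabulary tuples in the positive sequences.
    ``idf_i = log(|D| / (1 + df_i))`` over *all* training sequences. The
    logarithm is natural unless ``log_base`` is given.
    """
    if train.n_positive == 0 or train.n_negative == 0:
        raise ValueError("training set must contain both classes "
                         f"(got {train.n_positive}+ / {train.n_negative}-)")
    counts = count_matrix(train, vocab)
    pos_mask = train.labels == 1
    pos_total = counts[pos_mask].sum(axis=0)
    denom = pos_total.sum()
    if denom == 0:
        raise ValueError("positive training sequences contain no countable tuples")
    tf = pos_total / denom
    df = (counts > 0).sum(axis=0)
    n_docs = len(train)
    idf = np.log(n_docs / (1.0 + df))
    if log_base is not None:
        idf = idf / math.log(log_base)
    return TfIdfModel(tf=tf, idf=idf, tfidf=tf * idf, n_documents=n_docs,
                      doc_frequency=df.astype(np.int64),
                      k_min=vocab.k_min, k_max=vocab.k_max, log_base=log_base)


def transform_tfidf(model: TfIdfModel, seq_set: LabeledSequenceSet,
                    vocab: KmerVocabulary) -> "FeatureMatrix":
    """Encode each sequence as ``l_i = tfidf_i * n_i`` using frozen weights."""
    model.check_vocab(vocab)
    counts = count_matrix(seq_set, vocab)
    values = counts * model.tfidf[np.newaxis, :]
    columns = [f"tfidf:{e}" for e in vocab.entries]
    return FeatureMatrix(values=values.astype(float), columns=columns,
                         labels=seq_set.labels, ids=seq_set.ids)


# ---------------------------------------------------------------------------
# Base content
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseContentVector:
    """AT/GC profiles and skews of one sequence; N bases are excluded.

    A zero skew denominator yields skew 0 with the corresponding
    ``*_degenerate`` flag set, so single-composition toy inputs still work.
    """

    at_profile: float
    gc_profile: float
    gc_skew: float
    at_skew: float
    gc_degenerate: bool = False
    at_degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.at_profile, self.gc_profile,
                         self.gc_skew, self.at_skew])


BASE_CONTENT_COLUMNS = ("base:at_profile", "base:gc_profile",
                        "base:gc_skew", "base:at_skew")


def base_content(sequence: str) -> BaseContentVector:
    a = sequence.count("A")
    c = sequence.count("C")
    g = sequence.count("G")
    t = sequence.count("T")
    total = a + c + g + t
    if total == 0:
        raise ValueError("sequence has no countable (non-N) bases")
    at, gc = a + t, g + c
    gc_deg, at_deg = gc == 0, at == 0
    return BaseContentVector(
        at_profile=at / total,
        gc_profile=gc / total,
        gc_skew=0.0 if gc_deg else (g - c) / gc,
        at_skew=0.0 if at_deg else (a - t) / at,
        gc_degenerate=gc_deg,
        at_degenerate=at_deg,
    )


# ---------------------------------------------------------------------------
# PseKNC type II (series correlation)
# ---------------------------------------------------------------------------

_DINUCS = tuple(a + b for a in _BASES for b in _BASES)


def load_property_table(path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Load a dinucleotide physicochemical property table (raw values).

    Rows are the 16 dinucleotides, columns are property names. The packaged
    default table carries six B-DNA step parameters (twist, tilt, roll,
    shift, slide, rise); users may supply their own TSV with the same
    layout.
    """
    if path is None:
        ref = importlib.resources.files("oriseq.data") / "dinucleotide_properties.tsv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", index_col=0)
    else:
        table = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(_DINUCS) - set(table.index)
    if missing:
        raise ValueError(f"property table missing dinucleotides: {sorted(missing)}")
    return table.loc[list(_DINUCS)]


def standardize_properties(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each property over the 16 dinucleotides (population SD)."""
    mean = table.mean(axis=0)
    std = table.std(axis=0, ddof=0)
    if (std == 0).any():
        bad = list(std.index[std == 0])
        raise ValueError(f"property constant over dinucleotides: {bad}")
    return (table - mean) / std


@dataclass(frozen=True)
class PsekncConfig:
    """Configuration for the series-correlation encoder.

    ``lam`` (λ) is the number of correlation tiers, ``w`` the weight factor
    and ``properties`` a standardized table (mean 0, unit SD per property
    over the 16 dinucleotides).
    """

    k: int = 3
    lam: int = 2
    w: float = 0.5
    properties: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0 < self.w <= 1):
            raise ValueError("w must be in (0, 1]")
        if self.properties is None:
            object.__setattr__(self, "properties",
                               standardize_properties(load_property_table()))

    @property
    def n_properties(self) -> int:
        return self.properties.shape[1]

    @property
    def dimension(self) -> int:
        return 4 ** self.k + self.lam * self.n_properties


def _correlation_factors(sequence: str, config: PsekncConfig) -> np.ndarray:
    """θ_{j,q} for tiers j=1..λ and each property q.

    θ_{j,q} = (1/(L-j-1)) Σ_{m=1}^{L-j-1} H_q(s_m s_{m+1}) · H_q(s_{m+j} s_{m+j+1}).
    Pairs whose dinucleotides contain N are dropped from both sum and count.
    """
    L = len(sequence)
    props = config.properties.to_numpy()  # (16, Λ)
    dinuc_idx = np.full(L - 1, -1, dtype=np.int64)
    for m in range(L - 1):
        d = sequence[m:m + 2]
        if "N" not in d:
            dinuc_idx[m] = _DINUCS.index(d)
    theta = np.zeros((config.lam, config.n_properties))
    for j in range(1, config.lam + 1):
        left = dinuc_idx[:L - 1 - j]
        right = dinuc_idx[j:L - 1]
        valid = (left >= 0) & (right >= 0)
        if valid.sum() == 0:
            raise ValueError(f"no valid dinucleotide pair at tier {j}")
        h_left = props[left[valid]]
        h_right = props[right[valid]]
        theta[j - 1] = (h_left * h_right).sum(axis=0) / valid.sum()
    return theta


def pseknc2(sequence: str, config: PsekncConfig) -> np.ndarray:
    """Series-correlation pseudo k-tuple composition of one sequence.

    The first ``4^k`` entries are k-mer frequencies and the remaining
    ``λ·Λ`` entries weighted correlation factors, all divided by the shared
    normalizer ``1 + w·Σθ`` so the vector sums to 1. With λ = 0 the output
    is exactly the normalized k-mer composition.
    """
    L = len(sequence)
    if config.lam >= L - config.k:
        raise ValueError(
            f"lam={config.lam} must be < L - k = {L - config.k} "
            f"for a length-{L} sequence")
    vocab = build_vocabulary(config.k, config.k)
    counts = count_kmers(sequence, vocab).counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no countable k-tuples")
    freqs = counts / total
    if config.lam == 0:
        return freqs
    theta = _correlation_factors(sequence, config).ravel()  # tier-major
    denom = 1.0 + config.w * theta.sum()
    return np.concatenate([freqs / denom, config.w * theta / denom])


def pseknc_columns(config: PsekncConfig) -> list[str]:
    vocab = build_vocabulary(config.k, config.k)
    cols = [f"pseknc{config.k}:{e}" for e in vocab.entries]
    for j in range(1, config.lam + 1):
        for q in config.properties.columns:
            cols.append(f"pseknc{config.k}:theta{j}:{q}")
    return cols


# ---------------------------------------------------------------------------
# Feature matrix and the combined extractor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureMatrix:
    """Named feature columns for a sequence set, with binary labels."""

    values: np.ndarray
    columns: list[str]
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if v.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if v.shape[0] != len(self.labels) or v.shape[0] != len(self.ids):
            raise ValueError("row count mismatch")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column names")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.columns.index(n) for n in names]
        return FeatureMatrix(values=self.values[:, idx], columns=list(names),
                             labels=self.labels, ids=self.ids)

    @staticmethod
    def hstack(matrices: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not matrices:
            raise ValueError("nothing to concatenate")
        first = matrices[0]
        for m in matrices[1:]:
            if m.ids != first.ids or not np.array_equal(m.labels, first.labels):
                raise ValueError("matrices are not row-aligned")
        return FeatureMatrix(
            values=np.hstack([m.values for m in matrices]),
            columns=[c for m in matrices for c in m.columns],
            labels=first.labels, ids=first.ids)

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "id", self.ids)
        df["label"] = self.labels
        df.to_csv(path, sep="\t", index=False, float_format="%.17e")

    @staticmethod
    def from_tsv(path: str | os.PathLike) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        ids = df.pop("id").astype(str).tolist()
        labels = df.pop("label").to_numpy(dtype=np.int8)
        return FeatureMatrix(values=df.to_numpy(dtype=float),
                             columns=df.columns.tolist(), labels=labels, ids=ids)


KNOWN_METHODS = ("tfidf", "pseknc", "base_content")


def extract_features(
    seq_set: LabeledSequenceSet,
    method: str | list[str],
    *,
    vocab: KmerVocabulary | None = None,
    tfidf_model: TfIdfModel | None = None,
    pseknc_configs: list[PsekncConfig] | None = None,
) -> FeatureMatrix:
    """Extract one or several feature blocks and concatenate column-wise.

    For ``tfidf``, a fitted model may be supplied (frozen transform); if
    absent one is fitted on ``seq_set`` itself — appropriate only when
    ``seq_set`` is the training split.
    """
    methods = [method] if isinstance(method, str) else list(method)
    if not methods:
        raise ValueError("empty method list")
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise ValueError(f"unknown feature method(s): {unknown}")

    blocks: list[FeatureMatrix] = []
    for m in methods:
        if m == "tfidf":
            v = vocab or build_vocabulary(1, 6)
            model = tfidf_model or fit_tfidf(seq_set, v)
            blocks.append(transform_tfidf(model, seq_set, v))
        elif m == "base_content":
            values = np.array([base_content(r.sequence).as_array()
                               for r in seq_set.records])
            blocks.append(FeatureMatrix(values=values,
                                        columns=list(BASE_CONTENT_COLUMNS),
                                        labels=seq_set.labels, ids=seq_set.ids))
        elif m == "pseknc":
            configs = pseknc_configs or [PsekncConfig(k=k) for k in range(1, 7)]
            for cfg in configs:
                values = np.array([pseknc2(r.sequence, cfg)
                                   for r in seq_set.records])
                blocks.append(FeatureMatrix(values=values,
                                            columns=pseknc_columns(cfg),
                                            labels=seq_set.labels,
                                            ids=seq_set.ids))
    return blocks[0] if len(blocks) == 1 else FeatureMatrix.hstack(blocks)


@dataclass
class FeaturePipeline:
    """A refittable / freezable feature extractor for one species.

    ``fit`` learns whatever state the configured methods need (currently
    the TF-IDF weights) from a training set; ``transform`` applies the
    frozen state to any set, optionally restricted to selected columns.
    Used both for fold-safe refitting inside cross-validation and for
    cross-species transfer, where the source species' frozen pipeline is
    applied verbatim to the target sequences.
    """

    methods: list[str]
    k_min: int = 1
    k_max: int = 6
    pseknc_configs: list[PsekncConfig] | None = None
    selected_columns: list[str] | None = None
    vocab: KmerVocabulary | None = None
    tfidf_model: TfIdfModel | None = None

    def __post_init__(self) -> None:
        if isinstance(self.methods, str):
            self.methods = [self.methods]
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown feature method(s): {unknown}")

    @property
    def is_fitted(self) -> bool:
        return "tfidf" not in self.methods or self.tfidf_model is not None

    def fit(self, train: LabeledSequenceSet) -> "FeaturePipeline":
        if "tfidf" in self.methods:
            if self.vocab is None:
                self.vocab = build_vocabulary(self.k_min, self.k_max)
            self.tfidf_model = fit_tfidf(train, self.vocab)
        return self

    def transform(self, seq_set: LabeledSequenceSet) -> FeatureMatrix:
        if not self.is_fitted:
            raise ValueError("pipeline not fitted: TF-IDF model is missing")
        mat = extract_features(seq_set, self.methods, vocab=self.vocab,
                               tfidf_model=self.tfidf_model,
                               pseknc_configs=self.pseknc_configs)
        if self.selected_columns is not None:
            mat = mat.select_columns(self.selected_columns)
        return mat

    def fit_transform(self, train: LabeledSequenceSet) -> FeatureMatrix:
        return self.fit(train).transform(train)
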