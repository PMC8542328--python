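"""Synthetic two-class sequence generator.

Produces balanced origin-like / background sets in which the positive class
differs from the negative by planted short motifs and/or shifted AT/GC
composition skews — the two statistical signals the feature encoders are
designed to measure. No attempt is made to imitate replication biology.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from oriseq.sequence_io import (LabeledRecord, LabeledSequenceSet,
                                write_labeled_fasta)

_BASES = ("A", "C", "G", "T")

_UNIFORM = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


def skewed_composition(base: dict[str, float], *, gc_skew: float | None = None,
                       at_skew: float | None = None) -> dict[str, float]:
    """Reweight a composition to hit target skews while preserving profiles.

    For a target GC-skew s the G/C mass p = pG + pC is redistributed as
    pG = p(1+s)/2, pC = p(1−s)/2 (and analogously for A/T), which gives
    (pG−pC)/(pG+pC) = s exactly in expectation.
    """
    comp = dict(base)
    if gc_skew is not None:
        if not -1 <= gc_skew <= 1:
            raise ValueError("gc_skew target must be in [-1, 1]")
        p = comp["G"] + comp["C"]
        comp["G"] = p * (1 + gc_skew) / 2
        comp["C"] = p * (1 - gc_skew) / 2
    if at_skew is not None:
        if not -1 <= at_skew <= 1:
            raise ValueError("at_skew target must be in [-1, 1]")
        p = comp["A"] + comp["T"]
        comp["A"] = p * (1 + at_skew) / 2
        comp["T"] = p * (1 - at_skew) / 2
    return comp


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic species."""

    n_positive: int = 100
    n_negative: int = 100
    length: int = 300
    positive_composition: dict[str, float] = field(
        default_factory=lambda: dict(_UNIFORM))
    negative_composition: dict[str, float] = field(
        default_factory=lambda: dict(_UNIFORM))
    motif: str = "GGG"
    planting_rate: float = 1.0
    copies: int = 3
    positive_gc_skew: float | None = None
    positive_at_skew: float | None = None
    negative_gc_skew: float | None = None
    negative_at_skew: float | None = None
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("class sizes must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for name, comp in (("positive", self.positive_composition),
                           ("negative", self.negative_composition)):
            if set(comp) != set(_BASES):
                raise ValueError(f"{name} composition must cover A/C/G/T")
            if any(p < 0 for p in comp.values()):
                raise ValueError(f"{name} composition has negative probability")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} composition must sum to 1")
        if not 0 <= self.planting_rate <= 1:
            raise ValueError("planting_rate must be in [0, 1]")
        if self.motif and not set(self.motif) <= set(_BASES):
            raise ValueError("motif must be over A/C/G/T")
        if self.motif and len(self.motif) >= self.length:
            raise ValueError("motif must be shorter than the sequence length")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")

    def class_composition(self, label: str) -> dict[str, float]:
        if label == "positive":
            return skewed_composition(self.positive_composition,
                                      gc_skew=self.positive_gc_skew,
                                      at_skew=self.positive_at_skew)
        return skewed_composition(self.negative_composition,
                                  gc_skew=self.negative_gc_skew,
                                  at_skew=self.negative_at_skew)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _plant_motif(sequence: list[str], motif: str, copies: int,
                 rng: np.random.Generator, *, max_tries: int = 10000) -> None:
    """Overwrite ``copies`` non-overlapping motif occurrences in place."""
    L, m = len(sequence), len(motif)
    if copies * m > L:
        raise ValueError(
            f"{copies} copies of a {m}-mer cannot fit non-overlapping in "
            f"length {L}")
    occupied: list[tuple[int, int]] = []
    for _ in range(copies):
        for _try in range(max_tries):
            start = int(rng.integers(0, L - m + 1))
            if all(start + m <= lo or start >= hi for lo, hi in occupied):
                occupied.append((start, start + m))
                sequence[start:start + m] = list(motif)
                break
        else:
            raise ValueError("could not place non-overlapping motif copies "
                             f"after {max_tries} tries")


def generate(spec: SyntheticSpec) -> LabeledSequenceSet:
    """Draw a labeled set per the spec; byte-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[LabeledRecord] = []
    for label, n in (("positive", spec.n_positive), ("negative", spec.n_negative)):
        comp = spec.class_composition(label)
        probs = np.array([comp[b] for b in _BASES])
        for i in range(n):
            seq = list(rng.choice(_BASES, size=spec.length, p=probs))
            if label == "positive" and spec.motif and spec.copies > 0:
                if rng.random() < spec.planting_rate:
                    _plant_motif(seq, spec.motif, spec.copies, rng)
            records.append(LabeledRecord(
                id=f"{spec.species}_{label[:3]}_{i:05d}",
                sequence="".join(seq), label=label))
    return LabeledSequenceSet(records=tuple(records), species=spec.species)


def two_species(spec_a: SyntheticSpec,
                spec_b: SyntheticSpec) -> tuple[LabeledSequenceSet,
                                                LabeledSequenceSet]:
    """Two independent synthetic species (e.g. for transfer experiments)."""
    if spec_a == spec_b:
        warnings.warn("identical specs and seeds: the two species will "
                      "coincide", stacklevel=2)
    return generate(spec_a), generate(spec_b)


def generate_files(spec: SyntheticSpec, out_dir: str | os.PathLike,
                   *, prefix: str | None = None) -> tuple[str, str, str]:
    """Emit the two-file FASTA convention plus a JSON provenance sidecar.

    Returns ``(positive_path, negative_path, sidecar_path)``.
    """
    os.makedirs(out_dir, exist_ok=True)
    prefix = prefix or spec.species
    pos_path = os.path.join(out_dir, f"{prefix}_positive.fasta")
    neg_path = os.path.join(out_dir, f"{prefix}_negative.fasta")
    sidecar = os.path.join(out_dir, f"{prefix}_spec.json")
    seq_set = generate(spec)
    write_labeled_fasta(seq_set, pos_path, neg_path)
    with open(sidecar, "w") as fh:
        fh.write(spec.to_json() + "\n")
    return pos_path, neg_path, sidecar
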