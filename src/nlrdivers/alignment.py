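"""Aligned sequence containers.

Population alignments are the substrate for every per-gene statistic in this
package: per-column Shannon entropy is computed on protein alignments, and
nucleotide diversity / Tajima's D / piN-piS on in-frame codon alignments.
Sequences are stored as plain uppercase strings; all columns are index-0
internally, with 1-based coordinates only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = frozenset("ACGT")
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")
GAP_CHARS = frozenset("-.")

#: characters that carry no diversity information and are excluded from
#: residue tallies alongside gaps
PROTEIN_NONINFORMATIVE = GAP_CHARS | frozenset("X*")
NUCLEOTIDE_NONINFORMATIVE = GAP_CHARS | IUPAC_AMBIGUOUS


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, bad characters, ...)."""


@dataclass(frozen=True)
class Alignment:
    """An equal-length collection of named sequences.

    Parameters
    ----------
    records
        ``(sequence_id, residues)`` pairs; residue strings must share one
        length. Stored uppercased.
    alphabet
        ``"protein"`` or ``"nucleotide"``; controls which characters are
        legal and which are treated as non-informative.
    """

    records: tuple[tuple[str, str], ...]
    alphabet: str = "protein"
    gap_char: str = "-"

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "nucleotide"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        records = tuple((sid, seq.upper()) for sid, seq in self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise AlignmentError("alignment has no records")
        ids = [sid for sid, _ in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        length = len(records[0][1])
        for sid, seq in records:
            if len(seq) != length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(seq)}, expected {length}"
                )
        legal = self._legal_characters()
        for sid, seq in records:
            bad = set(seq) - legal
            if bad:
                raise AlignmentError(
                    f"record {sid!r} contains illegal characters {sorted(bad)}"
                )

    def _legal_characters(self) -> frozenset[str]:
        if self.alphabet == "protein":
            return PROTEIN_RESIDUES | PROTEIN_NONINFORMATIVE
        return NUCLEOTIDES | NUCLEOTIDE_NONINFORMATIVE

    @property
    def noninformative(self) -> frozenset[str]:
        if self.alphabet == "protein":
            return PROTEIN_NONINFORMATIVE
        return NUCLEOTIDE_NONINFORMATIVE

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def sequence_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.records)

    def columns(self) -> Iterator[str]:
        for i in range(self.length):
            yield self.column(i)

    def to_matrix(self) -> np.ndarray:
        """Character matrix of shape (n_sequences, length)."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(self.n_sequences, self.length)

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        """Subset to the given columns (order preserved).

        An empty index set yields a zero-length alignment; callers that
        require non-empty alignments must check ``length``.
        """
        idx = list(indices)
        new_records = tuple(
            (sid, "".join(seq[i] for i in idx)) for sid, seq in self.records
        )
        return _subset(self, new_records)

    def slice_columns(self, start: int, stop: int) -> "Alignment":
        """Columns ``start:stop`` (0-based, half-open)."""
        new_records = tuple((sid, seq[start:stop]) for sid, seq in self.records)
        return _subset(self, new_records)


def _subset(parent: Alignment, records: tuple[tuple[str, str], ...]) -> Alignment:
    cls = type(parent)
    obj = object.__new__(cls)
    object.__setattr__(obj, "records", records)
    object.__setattr__(obj, "alphabet", parent.alphabet)
    object.__setattr__(obj, "gap_char", parent.gap_char)
    if isinstance(obj, CodonAlignment):
        object.__setattr__(obj, "frame_offset", 0)
        if records and len(records[0][1]) % 3 != 0:
            raise AlignmentError("codon alignment subset length not divisible by 3")
    return obj


@dataclass(frozen=True)
class CodonAlignment(Alignment):
    """In-frame nucleotide alignment; length divisible by 3, frame offset 0."""

    alphabet: str = "nucleotide"
    frame_offset: int = field(default=0)

    def __post_init__(self) -> None:
        if self.alphabet != "nucleotide":
            raise AlignmentError("codon alignments must use the nucleotide alphabet")
        super().__post_init__()
        if self.frame_offset != 0:
            raise AlignmentError("only frame offset 0 is supported")
        if self.length % 3 != 0:
            raise AlignmentError(
                f"codon alignment length {self.length} not divisible by 3"
            )

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, seq_index: int, codon_index: int) -> str:
        seq = self.records[seq_index][1]
        return seq[3 * codon_index : 3 * codon_index + 3]
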