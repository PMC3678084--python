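"""Sequence primitives for siRNA design.

RNA-alphabet sequences with a 1-based coordinate convention (positions are
counted from the 5' end), reverse complementation, FASTA input/output, the
siRNA candidate geometry (23-nt target window -> 21-nt guide/passenger
strands with 2-nt 3' overhangs), and a reproducible synthetic-mRNA
generator used as a test-input source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sirnaselect")

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Length of the target-site window an siRNA duplex covers on the mRNA.
TARGET_WINDOW_LENGTH = 23
#: Length of each siRNA strand (19-bp duplex core + 2-nt 3' overhang).
SIRNA_STRAND_LENGTH = 21


class SequenceValidationError(ValueError):
    """Raised when input text cannot be interpreted as an A/C/G/U(T) sequence."""


def revcomp(residues: str) -> str:
    """Reverse complement of an RNA string (plain-string helper)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated RNA-alphabet sequence.

    Positions are 1-based from the 5' end throughout; use :meth:`at` and
    :meth:`region` rather than raw indexing when following positions quoted
    in design rules.
    """

    residues: str
    id: str = ""
    original_alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if self.original_alphabet not in ("RNA", "DNA"):
            raise SequenceValidationError(
                f"original_alphabet must be 'RNA' or 'DNA', got {self.original_alphabet!r}"
            )
        bad = next((i for i, c in enumerate(self.residues, start=1) if c not in RNA_ALPHABET), None)
        if bad is not None:
            raise SequenceValidationError(
                f"invalid residue {self.residues[bad - 1]!r} at position {bad}"
                f" in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def at(self, position: int) -> str:
        """Residue at a 1-based position from the 5' end."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]

    def region(self, start: int, end: int) -> str:
        """Residues in the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"interval {start}-{end} outside 1..{len(self.residues)}")
        return self.residues[start - 1 : end]


def normalize(raw: str, id: str = "") -> NucleotideSequence:
    """Normalize raw text to an RNA-alphabet :class:`NucleotideSequence`.

    Whitespace is stripped, letters are upper-cased and T is mapped to U.
    The original alphabet (DNA if any T was seen, otherwise RNA) is
    recorded.  IUPAC ambiguity codes (N, R, Y, ...) are rejected with a
    :class:`SequenceValidationError` naming the offending 1-based position:
    the design rules and the melting-temperature model are undefined on
    them, so the default is to fail loudly.
    """
    stripped = "".join(raw.split())
    if not stripped:
        raise SequenceValidationError(f"empty sequence for id {id!r}")
    upper = stripped.upper()
    bad = next((i for i, c in enumerate(upper, start=1) if c not in "ACGTU"), None)
    if bad is not None:
        raise SequenceValidationError(
            f"invalid character {upper[bad - 1]!r} at position {bad} in sequence {id!r}"
        )
    alphabet = "DNA" if "T" in upper else "RNA"
    return NucleotideSequence(upper.replace("T", "U"), id=id, original_alphabet=alphabet)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick RNA complement, reversed (5'->3' on the other strand)."""
    return NucleotideSequence(
        revcomp(seq.residues), id=seq.id, original_alphabet=seq.original_alphabet
    )


def read_fasta(path: Union[str, Path]) -> list[NucleotideSequence]:
    """Read a FASTA file into normalized sequences, preserving record order.

    Multi-line records are concatenated; duplicate ids are retained with a
    logged warning (downstream reports key on ``(id, window_start)``); an
    empty file yields an empty list with a warning; a record with an empty
    sequence is a validation error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("no FASTA records found in %s", path)
        return []
    seen: set[str] = set()
    out: list[NucleotideSequence] = []
    for rec in records:
        if rec.id in seen:
            logger.warning("duplicate FASTA id %r in %s; keeping both records", rec.id, path)
        seen.add(rec.id)
        out.append(normalize(str(rec.seq), id=rec.id))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: Union[str, Path]) -> None:
    """Write sequences to FASTA (RNA alphabet, as stored)."""
    records = [SeqRecord(Seq(s.residues), id=s.id or "sequence", description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def generate_synthetic_mrna(
    length: int, gc_fraction: float, seed: int, id: str | None = None
) -> NucleotideSequence:
    """Generate a random mRNA-like sequence with a prescribed GC content.

    Residues are drawn i.i.d. with P(G) = P(C) = ``gc_fraction``/2 and
    P(A) = P(U) = (1 - ``gc_fraction``)/2.  Output is bit-reproducible for
    identical ``(length, gc_fraction, seed)``.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_au = (1.0 - gc_fraction) / 2.0
    letters = rng.choice(np.array(list("ACGU")), size=length, p=[p_au, p_gc, p_gc, p_au])
    if id is None:
        id = f"synthetic_mrna_len{length}_gc{gc_fraction:g}_seed{seed}"
    return NucleotideSequence("".join(letters), id=id)


@dataclass(frozen=True)
class SiRNACandidate:
    """A 23-nt target window with its derived 21-nt guide and passenger strands.

    For a window ``w[1..23]`` (1-based) the passenger (sense) strand is
    ``w[3..23]`` and the guide (antisense) strand is the reverse complement
    of ``w[1..21]``: a 19-bp duplex core (guide positions 1-19 pairing
    ``w[3..21]``) with 2-nt 3' overhangs on both strands.  Guide position 1
    pairs ``w[21]``; the seed (guide positions 2-8) pairs ``w[14..20]``.
    """

    target_id: str
    window_start: int
    target_window: NucleotideSequence
    guide: NucleotideSequence
    passenger: NucleotideSequence

    def __post_init__(self) -> None:
        if len(self.target_window) != TARGET_WINDOW_LENGTH:
            raise SequenceValidationError(
                f"target window must be {TARGET_WINDOW_LENGTH} nt, got {len(self.target_window)}"
            )
        if len(self.guide) != SIRNA_STRAND_LENGTH or len(self.passenger) != SIRNA_STRAND_LENGTH:
            raise SequenceValidationError("guide and passenger strands must be 21 nt")
        w = self.target_window.residues
        if self.guide.residues != revcomp(w[:21]):
            raise SequenceValidationError("guide is not the reverse complement of window[1..21]")
        if self.passenger.residues != w[2:]:
            raise SequenceValidationError("passenger does not equal window[3..23]")
        if self.window_start < 1:
            raise SequenceValidationError("window_start must be >= 1")

    @classmethod
    def from_window(
        cls, window: Union[str, NucleotideSequence], target_id: str = "", window_start: int = 1
    ) -> "SiRNACandidate":
        """Build a candidate from a 23-nt target window."""
        if isinstance(window, str):
            window = normalize(window, id=target_id)
        w = window.residues
        if len(w) != TARGET_WINDOW_LENGTH:
            raise SequenceValidationError(
                f"target window must be {TARGET_WINDOW_LENGTH} nt, got {len(w)}"
            )
        guide = NucleotideSequence(revcomp(w[:21]), id=f"{target_id}:{window_start}:guide")
        passenger = NucleotideSequence(w[2:], id=f"{target_id}:{window_start}:passenger")
        return cls(
            target_id=target_id,
            window_start=window_start,
            target_window=window,
            guide=guide,
            passenger=passenger,
        )

    @property
    def seed(self) -> str:
        """Guide-strand seed region, positions 2-8 (7 nt, 5'->3')."""
        return self.guide.region(2, 8)
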