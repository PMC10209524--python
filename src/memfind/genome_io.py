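"""Multi-FASTA input as a single concatenated text with a sequence table.

A genome is held as one uppercase byte string in which consecutive
sequences are joined by a single non-nucleotide separator byte.  Because
exact-match extension requires *equal, unambiguous* nucleotides on both
sides, the separator can never participate in a match, so no match spans
two sequences.  All internal coordinates are 0-based offsets into the
concatenated text; conversion to 1-based per-sequence coordinates happens
only at output time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SEPARATOR",
    "SeqRecord",
    "Genome",
    "genome_from_sequences",
    "load_fasta",
    "min_record_length",
]

#: Byte placed between consecutive sequences; '>' is not an IUPAC code.
SEPARATOR = ord(">")

# 2-bit nucleotide codes; everything else (N, other IUPAC, separator) -> 255,
# which the matching layer treats as never-equal.
CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    CODE_TABLE[_c] = _i
INVALID_CODE = 255


@dataclass(frozen=True)
class SeqRecord:
    """One named sequence: absolute start offset and length in bases."""

    name: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """One past the last base (exclusive)."""
        return self.start + self.length


@dataclass
class Genome:
    """Concatenated genome text plus its sequence table."""

    text: bytes
    records: list[SeqRecord]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def total_length(self) -> int:
        return len(self.text)

    @property
    def codes(self) -> np.ndarray:
        """uint8 array: 0..3 for A/C/G/T, 255 for anything unmatchable."""
        if self._codes is None:
            self._codes = CODE_TABLE[np.frombuffer(self.text, dtype=np.uint8)]
        return self._codes

    def record_sequence(self, rec: SeqRecord) -> bytes:
        return self.text[rec.start : rec.end]


def genome_from_sequences(named_seqs: list[tuple[str, bytes | str]]) -> Genome:
    """Assemble a :class:`Genome` from ``(name, sequence)`` pairs.

    Sequences are uppercased and joined with one separator byte between
    consecutive records.  Zero-length sequences are dropped with a warning
    (they would make the shortest-sequence length 0, which the predecessor
    structure cannot sample).
    """
    kept: list[tuple[str, bytes]] = []
    for name, seq in named_seqs:
        if isinstance(seq, str):
            seq = seq.encode("ascii")
        seq = seq.upper()
        if len(seq) == 0:
            warnings.warn(f"dropping zero-length sequence {name!r}")
            continue
        kept.append((name, seq))
    if not kept:
        raise ValueError("no non-empty sequences")

    names = [n for n, _ in kept]
    if len(set(names)) != len(names):
        warnings.warn("duplicate sequence names in input; names kept verbatim")

    records: list[SeqRecord] = []
    parts: list[bytes] = []
    offset = 0
    for i, (name, seq) in enumerate(kept):
        if i > 0:
            parts.append(bytes([SEPARATOR]))
            offset += 1
        records.append(SeqRecord(name, offset, len(seq)))
        parts.append(seq)
        offset += len(seq)
    return Genome(b"".join(parts), records)


def load_fasta(path) -> Genome:
    """Read a multi-FASTA file into a :class:`Genome`.

    Headers are tokenized at the first whitespace; line wrapping and CRLF
    endings are tolerated.  Raises ``FileNotFoundError`` for a missing file
    and ``ValueError`` for a file with no sequences.
    """
    named: list[tuple[str, str]] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else ""
            named.append((name, seq))
    if not named:
        raise ValueError(f"{path}: no FASTA sequences found")
    return genome_from_sequences(named)


def min_record_length(g: Genome) -> int:
    """Length of the shortest sequence in the genome."""
    if not g.records:
        raise ValueError("genome has no records")
    return min(rec.length for rec in g.records)
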