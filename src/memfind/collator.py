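"""Block-wise collection, sorting, spilling and final output of matches.

The engine emits matches roughly — but not exactly — in query order, and
with duplicates.  Keeping every match of a large query sequence in memory
is wasteful, so matches are collected in a bounded block: when the block
fills, it is sorted and its first 3/4 is spilled to a temporary file while
the last 1/4 is retained as overlap, keeping the spill stream globally
sorted as long as no match arrives more than a quarter-block out of place.
If that assumption fails (a to-be-spilled key precedes the last spilled
key), a rescue re-reads the spill, merges, re-sorts and rewrites — slower
but never lossy.  Spill streams from all workers are k-way merged with
cross-stream deduplication into the final text output.

Matches are ordered by query start, then reference start.  Blocks above a
size threshold are sorted by an LSD radix pass over the high-order six
bytes of the packed (query, reference) key followed by a comparison sort
inside equal-prefix runs; small blocks use a plain comparison sort.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple

from .mem_engine import MatchTriple
from .predecessor_map import PredecessorMap
from .genome_io import SeqRecord

__all__ = [
    "CollatorConfig",
    "OutputRecord",
    "pack_key",
    "sort_block",
    "Collator",
    "merge_spills",
    "to_output_record",
    "write_output",
    "read_spill",
]

logger = logging.getLogger(__name__)

#: Bits per coordinate in the packed sort key (query high, reference low).
COORD_BITS = 40
_COORD_LIMIT = 1 << COORD_BITS

#: Fraction of a full block that is spilled (the rest is retained overlap).
DUMP_FRACTION = 0.75


@dataclass
class CollatorConfig:
    """Buffering and sorting knobs; none of them changes the output."""

    match_block: int = 1 << 21
    sort_threshold: int = 1024  # comparison sort at or below this size
    temp_dir: Path | None = None
    workers: int = 1

    def __post_init__(self) -> None:
        if self.match_block < 8 or self.match_block % 4:
            raise ValueError("match_block must be >= 8 and divisible by 4")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


class OutputRecord(NamedTuple):
    """One output line: 1-based per-sequence coordinates."""

    ref_name: str
    ref_pos: int
    q_pos: int
    length: int


def pack_key(t: MatchTriple) -> int:
    """Packed integer whose order equals (q_start, r_start) lexicographic."""
    if t.q_start >= _COORD_LIMIT or t.r_start >= _COORD_LIMIT:
        raise OverflowError(
            f"coordinate exceeds {COORD_BITS}-bit packed key limit {_COORD_LIMIT}"
        )
    return (t.q_start << COORD_BITS) | t.r_start


# The packed key is 80 bits; the radix pass covers its top 48 (the whole
# query coordinate plus the top byte of the reference coordinate), after
# which equal-prefix runs are finished with a comparison sort.
_RADIX_LOW_SHIFT = 2 * COORD_BITS - 48


def _radix_sort(triples: list[MatchTriple]) -> list[MatchTriple]:
    keyed = [(pack_key(t), t) for t in triples]
    for shift in range(_RADIX_LOW_SHIFT, 2 * COORD_BITS, 8):  # LSD: 6 byte passes
        buckets: list[list] = [[] for _ in range(256)]
        for kt in keyed:
            buckets[(kt[0] >> shift) & 0xFF].append(kt)
        keyed = [kt for b in buckets for kt in b]
    out: list[MatchTriple] = []
    i = 0
    n = len(keyed)
    while i < n:
        prefix = keyed[i][0] >> _RADIX_LOW_SHIFT
        j = i + 1
        while j < n and keyed[j][0] >> _RADIX_LOW_SHIFT == prefix:
            j += 1
        run = keyed[i:j]
        if len(run) > 1:
            run.sort(key=lambda kt: kt[0])
        out.extend(t for _, t in run)
        i = j
    return out


def sort_block(triples: list[MatchTriple], cfg: CollatorConfig) -> list[MatchTriple]:
    """Sort ascending by packed key; algorithm chosen by block size.

    Both paths produce identical results; the threshold only trades speed.
    """
    if len(triples) <= cfg.sort_threshold:
        return sorted(triples, key=pack_key)
    return _radix_sort(triples)


def _write_triple(fh: IO[str], t: MatchTriple) -> None:
    fh.write(f"{t.q_start} {t.r_start} {t.length}\n")


def read_spill(path: Path) -> Iterator[MatchTriple]:
    """Stream triples back from a spill file."""
    with open(path) as fh:
        for line in fh:
            q, r, ln = line.split()
            yield MatchTriple(int(r), int(q), int(ln))


class Collator:
    """Per-worker match collection with block-wise sort/spill and rescue.

    Triples for one query sequence are pushed between
    :meth:`begin_sequence` / :meth:`end_sequence`; each sequence yields one
    internally sorted, duplicate-free spill file.
    """

    def __init__(self, cfg: CollatorConfig, spill_dir: Path) -> None:
        self.cfg = cfg
        self.spill_dir = Path(spill_dir)
        self.rescues = 0
        self.blocks_dumped = 0
        self._buf: list[MatchTriple] = []
        self._fh: IO[str] | None = None
        self._path: Path | None = None
        self._last_spilled: MatchTriple | None = None

    def begin_sequence(self, tag: str) -> None:
        if self._fh is not None:
            raise RuntimeError("previous sequence not finalized")
        self._path = self.spill_dir / f"{tag}.spill"
        self._fh = open(self._path, "w")
        self._buf = []
        self._last_spilled = None

    def push(self, t: MatchTriple) -> None:
        self._buf.append(t)
        if len(self._buf) >= self.cfg.match_block:
            self._dump_block()

    def _spill_sorted(self, triples: list[MatchTriple]) -> None:
        """Write an already-sorted run, deduping against the stream tail."""
        assert self._fh is not None
        last = self._last_spilled
        for t in triples:
            if last is not None:
                if t == last:
                    continue
                if pack_key(t) < pack_key(last):
                    # Overlap was insufficient; rebuild the stream.
                    self._rescue(triples[triples.index(t):])
                    return
            _write_triple(self._fh, t)
            last = t
        self._last_spilled = last

    def _dump_block(self) -> None:
        self._buf = sort_block(self._buf, self.cfg)
        n_dump = (self.cfg.match_block * 3) // 4
        to_spill = self._buf[:n_dump]
        self._buf = self._buf[n_dump:]
        self._spill_sorted(to_spill)
        self.blocks_dumped += 1

    def _rescue(self, pending: list[MatchTriple]) -> None:
        """Re-sort everything spilled so far together with pending triples.

        Called when a to-be-spilled key precedes the last spilled key; the
        whole current-sequence stream is re-read, merged, sorted, deduped
        and rewritten.  Correct for any input order, just slower.
        """
        assert self._fh is not None and self._path is not None
        self.rescues += 1
        logger.warning(
            "out-of-order spill detected for %s; rescuing (consider a larger "
            "match block)",
            self._path.name,
        )
        self._fh.close()
        everything = list(read_spill(self._path)) + list(pending)
        everything = sort_block(everything, self.cfg)
        self._fh = open(self._path, "w")
        last = None
        for t in everything:
            if t != last:
                _write_triple(self._fh, t)
                last = t
        self._last_spilled = last

    def end_sequence(self) -> Path:
        """Sort and spill the remainder; returns the finished spill file."""
        if self._fh is None:
            raise RuntimeError("no sequence in progress")
        if self._buf:
            self._spill_sorted(sort_block(self._buf, self.cfg))
            self._buf = []
        self._fh.close()
        path = self._path
        self._fh = None
        self._path = None
        self._last_spilled = None
        return path


def merge_spills(paths: list[Path]) -> Iterator[MatchTriple]:
    """Streaming k-way merge of sorted spill files with cross-file dedup."""
    streams = [read_spill(p) for p in paths]
    last: MatchTriple | None = None
    for t in heapq.merge(*streams, key=pack_key):
        if t != last:
            yield t
            last = t


def to_output_record(
    t: MatchTriple, r_map: PredecessorMap, q_record: SeqRecord
) -> OutputRecord:
    """Convert absolute coordinates to 1-based per-sequence coordinates."""
    rec = r_map.locate(t.r_start)
    if not (q_record.start <= t.q_start < q_record.end):
        raise ValueError(
            f"query start {t.q_start} outside record {q_record.name!r}"
        )
    return OutputRecord(
        ref_name=rec.name,
        ref_pos=t.r_start - rec.start + 1,
        q_pos=t.q_start - q_record.start + 1,
        length=t.length,
    )


def write_output(
    groups: Iterable[tuple[SeqRecord, Iterable[OutputRecord]]], sink: IO[str]
) -> int:
    """Write the final per-query-sequence match listing.

    One header line per query sequence (emitted even with zero matches,
    mirroring the MUMmer-family convention), then one tab-separated line
    per MEM: reference sequence name, 1-based reference position, 1-based
    query position, length.  Returns the number of match lines written.
    """
    n = 0
    for q_record, records in groups:
        sink.write(f"> {q_record.name}\n")
        for r in records:
            sink.write(f" {r.ref_name}\t{r.ref_pos}\t{r.q_pos}\t{r.length}\n")
            n += 1
    return n
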