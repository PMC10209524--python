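"""Constant-time mapping from an absolute position to its sequence.

Output needs per-sequence coordinates, so every MEM start must be mapped
to the sequence containing it — a predecessor query over the sorted
sequence starts.  Instead of a binary search per MEM, a static array Beg
of length floor(|G|/step) + 1 (i.e. ceil((|G|+0.5)/step)) holds, for each
cell c, the last record whose start is <= c*step.  Because the step never
exceeds the shortest sequence length, at most one record boundary falls
inside a cell, so a query inspects Beg[pos // step] and at most one
successor.  The production step is the largest power of two not greater
than the shortest sequence length, turning the division into a shift.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome, SeqRecord, min_record_length

__all__ = [
    "effective_step",
    "PredecessorMap",
    "build_predecessor",
    "locate_sequence",
]

#: Fall back to binary search when Beg would exceed this many cells.
DEFAULT_CELL_BUDGET = 1 << 27


def effective_step(lmin: int) -> int:
    """Largest power of two not greater than the shortest sequence length."""
    if lmin < 1:
        raise ValueError(f"shortest sequence length must be >= 1, got {lmin}")
    return 1 << (lmin.bit_length() - 1)


@dataclass
class PredecessorMap:
    """Sampled predecessor array over a genome's sequence starts."""

    records: list[SeqRecord]
    total_length: int
    step: int
    shift: int | None  # log2(step) when step is a power of two
    beg: np.ndarray | None  # record indices; None => binary-search fallback
    _starts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._starts is None:
            self._starts = np.array([r.start for r in self.records], dtype=np.int64)

    @classmethod
    def from_records(
        cls,
        records: list[SeqRecord],
        total_length: int,
        step: int,
        cell_budget: int = DEFAULT_CELL_BUDGET,
    ) -> "PredecessorMap":
        if not records:
            raise ValueError("no records")
        lmin = min(r.length for r in records)
        if not (1 <= step <= lmin):
            raise ValueError(
                f"step {step} must lie in [1, shortest sequence length {lmin}]"
            )
        n_cells = total_length // step + 1
        if n_cells > cell_budget:
            warnings.warn(
                f"predecessor array would need {n_cells} cells "
                f"(budget {cell_budget}); falling back to binary search"
            )
            beg = None
        else:
            # Linear sweep: cell c holds the last record with start <= c*step.
            beg = np.empty(n_cells, dtype=np.int64)
            ri = 0
            for c in range(n_cells):
                pos = c * step
                while ri + 1 < len(records) and records[ri + 1].start <= pos:
                    ri += 1
                beg[c] = ri
        shift = step.bit_length() - 1 if step & (step - 1) == 0 else None
        return cls(
            records=list(records),
            total_length=total_length,
            step=step,
            shift=shift,
            beg=beg,
        )

    @classmethod
    def for_genome(cls, g: Genome, cell_budget: int = DEFAULT_CELL_BUDGET) -> "PredecessorMap":
        """Production structure: step = effective_step(shortest length)."""
        return cls.from_records(
            g.records, g.total_length, effective_step(min_record_length(g)), cell_budget
        )

    def locate(self, pos: int) -> SeqRecord:
        """The unique sequence record containing absolute position ``pos``."""
        if not (0 <= pos < self.total_length):
            raise IndexError(f"position {pos} outside [0, {self.total_length})")
        if self.beg is None:
            ri = bisect_right(self._starts, pos) - 1
        else:
            c = pos >> self.shift if self.shift is not None else pos // self.step
            ri = int(self.beg[c])
            if ri + 1 < len(self.records) and pos >= self.records[ri + 1].start:
                ri += 1
        rec = self.records[ri]
        if pos >= rec.end:
            raise ValueError(f"position {pos} falls on a separator, not in a sequence")
        return rec


def build_predecessor(g: Genome, step: int) -> PredecessorMap:
    """Build the sampled predecessor array for a genome at a given step."""
    return PredecessorMap.from_records(g.records, g.total_length, step)


def locate_sequence(m: PredecessorMap, pos: int) -> SeqRecord:
    return m.locate(pos)
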