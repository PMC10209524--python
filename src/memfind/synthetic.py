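"""Synthetic genome pairs and a brute-force MEM oracle.

The generator emulates the regime the finder targets: multi-sequence
genomes and mutated near-copies of them (point substitutions, short
indels, runs of Ns), standing in for same-species genome pairs at desk
scale.  The oracle enumerates every diagonal of the (reference, query)
grid and reports each maximal run of matching unambiguous nucleotides of
length >= L — exact, duplicate-free and independent of the sampled
seed-and-extend path it is used to check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import INVALID_CODE, Genome, genome_from_sequences
from .mem_engine import MatchTriple

__all__ = [
    "MutationModel",
    "generate_genome",
    "mutate_genome",
    "oracle_mems",
    "fixture_pair",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ZERO = np.zeros(1, dtype=np.int8)

#: Diagonal-scan size guard: |R| * |Q| cell-equivalents.
MAX_ORACLE_CELLS = 2 * 10**8


@dataclass(frozen=True)
class MutationModel:
    """Per-base mutation process applied independently to each sequence."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    max_indel_len: int = 5
    n_run_rate: float = 0.0
    n_run_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.substitution_rate,
            self.insertion_rate,
            self.deletion_rate,
            self.n_run_rate,
        ):
            if not (0.0 <= r < 1.0):
                raise ValueError(f"rate {r} outside [0, 1)")


def generate_genome(
    n_seqs: int,
    lengths: int | list[int],
    seed: int,
    names: list[str] | None = None,
) -> Genome:
    """I.i.d. uniform-ACGT genome with the given sequence lengths.

    Deterministic per seed.  ``lengths`` may be a single value applied to
    every sequence or one value per sequence.
    """
    if n_seqs < 1:
        raise ValueError("need at least one sequence")
    if isinstance(lengths, int):
        lengths = [lengths] * n_seqs
    if len(lengths) != n_seqs:
        raise ValueError("one length per sequence required")
    if names is None:
        names = [f"seq{i + 1}" for i in range(n_seqs)]
    rng = np.random.default_rng(seed)
    named = []
    for name, n in zip(names, lengths):
        seq = _BASES[rng.integers(0, 4, size=n)].tobytes()
        named.append((name, seq))
    return genome_from_sequences(named)


def _mutate_sequence(seq: bytes, m: MutationModel, rng: np.random.Generator) -> bytes:
    arr = np.frombuffer(seq, dtype=np.uint8).copy()
    n = len(arr)

    # Substitutions: each A/C/G/T base flips to one of the three others.
    if m.substitution_rate > 0:
        from .genome_io import CODE_TABLE

        codes = CODE_TABLE[arr]
        hit = (rng.random(n) < m.substitution_rate) & (codes != INVALID_CODE)
        idx = np.flatnonzero(hit)
        if idx.size:
            new_codes = (codes[idx] + 1 + rng.integers(0, 3, size=idx.size)) % 4
            arr[idx] = _BASES[new_codes]

    # Structural events, applied left to right; overlapping events are
    # dropped so record boundaries and determinism stay simple.
    events: list[tuple[int, int]] = []  # (pos, kind) kinds: 0 del, 1 ins, 2 N-run
    if m.deletion_rate > 0:
        events += [(int(p), 0) for p in np.flatnonzero(rng.random(n) < m.deletion_rate)]
    if m.insertion_rate > 0:
        events += [(int(p), 1) for p in np.flatnonzero(rng.random(n) < m.insertion_rate)]
    if m.n_run_rate > 0:
        events += [(int(p), 2) for p in np.flatnonzero(rng.random(n) < m.n_run_rate)]
    if not events:
        return arr.tobytes()

    events.sort()
    pieces: list[bytes] = []
    prev = 0
    for pos, kind in events:
        if pos < prev:
            continue
        pieces.append(arr[prev:pos].tobytes())
        if kind == 0:
            dlen = int(rng.integers(1, m.max_indel_len + 1))
            prev = min(pos + dlen, n)
        elif kind == 1:
            ilen = int(rng.integers(1, m.max_indel_len + 1))
            pieces.append(_BASES[rng.integers(0, 4, size=ilen)].tobytes())
            prev = pos
        else:
            rlen = min(m.n_run_len, n - pos)
            pieces.append(b"N" * rlen)
            prev = pos + rlen
    pieces.append(arr[prev:].tobytes())
    return b"".join(pieces)


def mutate_genome(g: Genome, m: MutationModel) -> Genome:
    """Mutated near-copy: same record names/count, perturbed sequences.

    Deterministic per ``m.seed``.  Sequences that mutate to zero length are
    kept as a single N so the record count is preserved.
    """
    rng = np.random.default_rng(m.seed)
    named = []
    for rec in g.records:
        seq = _mutate_sequence(g.record_sequence(rec), m, rng)
        if not seq:
            seq = b"N"
        named.append((rec.name, seq))
    return genome_from_sequences(named)


def oracle_mems(
    R: Genome, Q: Genome, L: int, max_cells: int = MAX_ORACLE_CELLS
) -> set[MatchTriple]:
    """Ground-truth MEM set by exhaustive diagonal scanning.

    For every diagonal of the (R, Q) grid, maximal runs of equal
    unambiguous nucleotides of length >= L are reported.  Separators and
    ambiguity codes break runs on both sides, so per-sequence maximality
    is automatic.  Quadratic: guarded at ``max_cells`` cell-equivalents
    (larger inputs need a suffix-structure oracle, not provided here).
    """
    rc, qc = R.codes, Q.codes
    nr, nq = len(rc), len(qc)
    if nr * nq > max_cells:
        raise ValueError(
            f"|R|*|Q| = {nr * nq} exceeds the diagonal-scan guard {max_cells}; "
            "use a suffix-structure oracle for fixtures this large"
        )
    if L < 1:
        raise ValueError("L must be >= 1")
    mems: set[MatchTriple] = set()
    for d in range(-(nq - 1), nr):
        rs = max(d, 0)
        qs = rs - d
        n = min(nr - rs, nq - qs)
        if n < L:
            continue
        a = rc[rs : rs + n]
        b = qc[qs : qs + n]
        match = ((a == b) & (a != INVALID_CODE)).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate((_ZERO, match, _ZERO))))
        starts, ends = edges[::2], edges[1::2]
        lens = ends - starts
        for s, ln in zip(starts[lens >= L], lens[lens >= L]):
            mems.add(MatchTriple(rs + int(s), qs + int(s), int(ln)))
    return mems


def fixture_pair(
    seed: int,
    lengths: int | list[int] = (6000, 2500, 1500),
    divergence: float = 0.01,
    indel_rate: float = 0.0005,
    n_run_rate: float = 0.0,
) -> tuple[Genome, Genome]:
    """Reference plus mutated near-copy, the standard test condition.

    ``divergence`` is the per-base substitution rate; a small indel rate
    breaks collinearity so matches occur off the main diagonal.
    """
    if isinstance(lengths, tuple):
        lengths = list(lengths)
    R = generate_genome(
        n_seqs=len(lengths) if isinstance(lengths, list) else 1,
        lengths=lengths,
        seed=seed,
    )
    m = MutationModel(
        substitution_rate=divergence,
        insertion_rate=indel_rate,
        deletion_rate=indel_rate,
        n_run_rate=n_run_rate,
        seed=seed + 10_007,
    )
    return R, mutate_genome(R, m)


def write_fasta(g: Genome, path: Path | str, width: int = 70) -> None:
    """Write a genome back out as multi-FASTA (fixture materialization)."""
    with open(path, "w") as fh:
        for rec in g.records:
            fh.write(f">{rec.name}\n")
            seq = g.record_sequence(rec)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width].decode("ascii"))
                fh.write("\n")
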