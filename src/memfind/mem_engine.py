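"""Seed-and-extend MEM finding over the sampled query.

Every query position that is a multiple of k2 is probed against the
reference seed index; candidates are verified textually (hash collisions
rejected), extended maximally left and right, filtered at the minimum MEM
length L, and emitted.  A per-diagonal containment cache skips candidate
seeds that lie wholly inside an already-extended run on the same diagonal
— the extension through such a seed provably reproduces that run, so the
skip is lossless.  The emitted multiset may contain duplicates (the same
MEM reached from several seeds); deduplication is the collator's job.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np

from .genome_io import INVALID_CODE, Genome
from .params import Params
from .seed_index import SeedIndex, hash_positions

__all__ = [
    "MatchTriple",
    "DiagonalCache",
    "chars_match",
    "extend_seed",
    "containment_skip",
    "scan_query",
    "ConfigMismatchError",
]

_ACGT = frozenset(b"ACGT")


class ConfigMismatchError(ValueError):
    """Seed index was built with different parameters than the scan uses."""


class MatchTriple(NamedTuple):
    """One MEM in absolute 0-based concatenated coordinates."""

    r_start: int
    q_start: int
    length: int


def chars_match(a, b) -> bool:
    """True iff the two bytes are equal and unambiguous nucleotides.

    N/N, separator/separator and any pair involving an ambiguity code are
    non-matches, so runs can never cross a separator or an N.
    """
    if isinstance(a, (bytes, str)):
        a = ord(a)
    if isinstance(b, (bytes, str)):
        b = ord(b)
    return a == b and a in _ACGT


class DiagonalCache:
    """Most recent extended run per diagonal d = r_start - q_start."""

    __slots__ = ("_runs",)

    def __init__(self) -> None:
        self._runs: dict[int, tuple[int, int]] = {}

    def record(self, diagonal: int, q_start: int, q_end: int) -> None:
        self._runs[diagonal] = (q_start, q_end)

    def get(self, diagonal: int) -> tuple[int, int] | None:
        return self._runs.get(diagonal)

    def clear(self) -> None:
        self._runs.clear()

    def __len__(self) -> int:
        return len(self._runs)


def containment_skip(cache: DiagonalCache, i: int, j: int, K: int) -> bool:
    """Skip seed (i, j) if it lies inside a cached run on diagonal i - j.

    The cached run matched along its whole diagonal, so if it covers query
    interval [j, j+K) the seed's K-mer is guaranteed to match at i and its
    extension is exactly the cached run: re-extending is redundant.
    Different diagonals are never skipped.
    """
    run = cache.get(i - j)
    if run is None:
        return False
    qs, qe = run
    return qs <= j and j + K <= qe


def _extend_right(rc: np.ndarray, qc: np.ndarray, i: int, j: int) -> int:
    """Matching characters at (i+t, j+t) for t = 0.. until first non-match."""
    limit = min(len(rc) - i, len(qc) - j)
    t = 0
    window = 64
    while t < limit:
        w = min(window, limit - t)
        a = rc[i + t : i + t + w]
        b = qc[j + t : j + t + w]
        stop = np.flatnonzero((a != b) | (a == INVALID_CODE))
        if stop.size:
            return t + int(stop[0])
        t += w
        window *= 2
    return limit


def _extend_left(rc: np.ndarray, qc: np.ndarray, i: int, j: int) -> int:
    """Matching characters at (i-1-t, j-1-t) going leftwards."""
    limit = min(i, j)
    t = 0
    window = 64
    while t < limit:
        w = min(window, limit - t)
        a = rc[i - t - w : i - t]
        b = qc[j - t - w : j - t]
        mism = (a != b) | (a == INVALID_CODE)
        stop = np.flatnonzero(mism[::-1])
        if stop.size:
            return t + int(stop[0])
        t += w
        window *= 2
    return limit


def extend_seed(
    R: Genome, Q: Genome, i: int, j: int, K: int, L: int | None = None
) -> MatchTriple | None:
    """Maximal run through the verified seed R[i:i+K) == Q[j:j+K).

    Extends left and right while characters match (equal and ACGT); returns
    None when ``L`` is given and the run is shorter.  The run is unique for
    the diagonal/seed pair, so any seed inside it yields the same triple.
    """
    rc, qc = R.codes, Q.codes
    right = _extend_right(rc, qc, i + K, j + K)
    left = _extend_left(rc, qc, i, j)
    length = left + K + right
    if L is not None and length < L:
        return None
    return MatchTriple(i - left, j - left, length)


def scan_query(
    R: Genome,
    Q: Genome,
    idx: SeedIndex,
    p: Params,
    emit: Callable[[MatchTriple], None],
    *,
    probe_positions: np.ndarray | None = None,
    containment: bool = True,
    cache: DiagonalCache | None = None,
    stats: dict | None = None,
) -> None:
    """Probe sampled query positions, verify, extend, filter, emit.

    ``probe_positions`` restricts the scan to a subset of the absolute
    multiples of k2 (used for worker partitioning); positions must be
    increasing.  The caller is responsible for clearing/limiting the cache
    scope per query sequence — by default a fresh cache is used per call.
    """
    if idx.K != p.K or idx.k1 != p.k1:
        raise ConfigMismatchError(
            f"index built with (K={idx.K}, k1={idx.k1}) but scan uses "
            f"(K={p.K}, k1={p.k1})"
        )
    K, k2, L = p.K, p.k2, p.L
    nq = Q.total_length
    if probe_positions is None:
        if nq < K:
            return
        probe_positions = np.arange(0, nq - K + 1, k2, dtype=np.int64)
    else:
        probe_positions = np.asarray(probe_positions, dtype=np.int64)
        if np.any(probe_positions % k2):
            raise ValueError("probe positions must be multiples of k2")
    if len(probe_positions) == 0:
        return

    valid, bucket_ids = hash_positions(Q, probe_positions, K, idx.bucket_bits)
    rc, qc = R.codes, Q.codes
    rtext, qtext = R.text, Q.text
    if cache is None:
        cache = DiagonalCache()

    for jj in range(len(probe_positions)):
        if not valid[jj]:
            continue
        j = int(probe_positions[jj])
        if stats is not None:
            stats["seeds_probed"] = stats.get("seeds_probed", 0) + 1
        candidates = idx.lookup_bucket(int(bucket_ids[jj]))
        if candidates is None:
            continue
        kmer = qtext[j : j + K]
        for ip in candidates:
            i = int(ip)
            if containment and containment_skip(cache, i, j, K):
                continue
            if rtext[i : i + K] != kmer:
                continue  # hash collision
            if stats is not None:
                stats["candidates_verified"] = stats.get("candidates_verified", 0) + 1
            right = _extend_right(rc, qc, i + K, j + K)
            left = _extend_left(rc, qc, i, j)
            length = left + K + right
            q0 = j - left
            cache.record(i - j, q0, q0 + length)
            if length >= L:
                emit(MatchTriple(i - left, q0, length))
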