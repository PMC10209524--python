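"""Hash table over K-mers sampled every k1 positions of the reference.

The table is a chained hash: 2**bucket_bits buckets, each holding the
sorted list of sampled reference positions whose K-mer hashes there.
Collisions are allowed; callers must verify textual equality before
extending.  Positions whose K-mer contains any non-ACGT byte (including
the inter-sequence separator) are never stored.

The hash is a fixed multiply-xorshift (splitmix64 finalizer) over the
2-bit packing of the K-mer, chosen for determinism across runs and
platforms; any well-dispersing function would do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import CODE_TABLE, INVALID_CODE, Genome
from .params import MEMORY_FRUGAL, Params

__all__ = [
    "hash_kmer",
    "default_bucket_bits",
    "SeedIndex",
    "build_index",
    "hash_positions",
]

_MASK64 = (1 << 64) - 1

#: Cap on table size (2**26 buckets) and the memory-frugal reduction.
_MAX_BUCKET_BITS = 26
_MF_BITS_DELTA = 2


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _splitmix64_vec(x: np.ndarray) -> np.ndarray:
    x = x + np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def hash_kmer(kmer: bytes | str, bucket_bits: int) -> int:
    """Bucket id in [0, 2**bucket_bits) for a clean ACGT K-mer.

    Deterministic: depends only on the 2-bit packing of the K-mer and on
    ``bucket_bits``.  Raises ``ValueError`` on non-ACGT input.
    """
    if isinstance(kmer, str):
        kmer = kmer.encode("ascii")
    packed = 0
    for c in kmer:
        code = int(CODE_TABLE[c])
        if code == INVALID_CODE:
            raise ValueError(f"non-ACGT byte {chr(c)!r} in k-mer")
        packed = (packed << 2) | code
    lo = packed & _MASK64
    hi = packed >> 64
    mixed = _splitmix64((lo ^ _splitmix64(hi)) & _MASK64)
    if bucket_bits <= 0:
        return 0
    return mixed >> (64 - bucket_bits)


def hash_positions(
    g: Genome, positions: np.ndarray, K: int, bucket_bits: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cleanliness + bucket ids for K-mers at given positions.

    Returns ``(valid, buckets)``: ``valid[i]`` is True when the K-mer at
    ``positions[i]`` fits in the text and contains only A/C/G/T; buckets of
    invalid positions are meaningless.  Bit-identical to :func:`hash_kmer`.
    """
    codes = g.codes
    n = len(codes)
    positions = np.asarray(positions, dtype=np.int64)
    in_range = positions + K <= n
    bad = np.concatenate(([0], np.cumsum(codes == INVALID_CODE, dtype=np.int64)))
    pend = np.minimum(positions + K, n)
    pstart = np.minimum(positions, n)
    valid = in_range & (bad[pend] - bad[pstart] == 0)

    pos_v = positions.copy()
    pos_v[~valid] = 0  # safe dummy reads
    lo = np.zeros(len(positions), dtype=np.uint64)
    hi = np.zeros(len(positions), dtype=np.uint64)
    for t in range(K):
        shift = 2 * (K - 1 - t)
        idx = np.minimum(pos_v + t, n - 1)
        c = codes[idx].astype(np.uint64)
        c[c == INVALID_CODE] = 0
        if shift >= 64:
            hi |= c << np.uint64(shift - 64)
        else:
            lo |= c << np.uint64(shift)
    mixed = _splitmix64_vec(lo ^ _splitmix64_vec(hi))
    if bucket_bits <= 0:
        buckets = np.zeros(len(positions), dtype=np.uint64)
    else:
        buckets = mixed >> np.uint64(64 - bucket_bits)
    return valid, buckets


def default_bucket_bits(n_sampled: int, mode: str = "default") -> int:
    """Table sizing: ~2 bits of address per sampled position, capped at 26.

    Memory-frugal mode shrinks the table by 2 bits (4x fewer buckets);
    longer chains cost only verification time, never completeness.
    """
    if n_sampled <= 1:
        bits = 1
    else:
        bits = min(2 * int(np.ceil(np.log2(n_sampled))), _MAX_BUCKET_BITS)
    if mode == MEMORY_FRUGAL:
        bits = max(bits - _MF_BITS_DELTA, 1)
    return bits


@dataclass
class SeedIndex:
    """Chained hash over sampled reference K-mer positions."""

    bucket_bits: int
    K: int
    k1: int
    n_positions: int
    buckets: dict[int, np.ndarray] = field(repr=False, default_factory=dict)

    def lookup(self, kmer: bytes | str) -> list[int]:
        """Candidate reference positions for a query K-mer.

        May contain hash-collision false positives; callers must verify
        textual equality.  Non-ACGT K-mers yield no candidates.
        """
        if isinstance(kmer, str):
            kmer = kmer.encode("ascii")
        if len(kmer) != self.K:
            raise ValueError(f"k-mer length {len(kmer)} != K={self.K}")
        try:
            b = hash_kmer(kmer, self.bucket_bits)
        except ValueError:
            return []
        arr = self.buckets.get(b)
        return [] if arr is None else [int(p) for p in arr]

    def lookup_bucket(self, bucket: int) -> np.ndarray | None:
        return self.buckets.get(bucket)

    def occupancy_histogram(self) -> dict[int, int]:
        """Bucket-load histogram (chain length -> number of buckets)."""
        hist: dict[int, int] = {}
        for arr in self.buckets.values():
            hist[len(arr)] = hist.get(len(arr), 0) + 1
        return hist


def build_index(R: Genome, p: Params, bucket_bits: int | None = None) -> SeedIndex:
    """Index every clean K-mer at reference positions that are multiples of k1.

    The stored position set is exactly {q : q % k1 == 0, q + K <= |R|,
    R[q:q+K] all ACGT}; no capping or dropping, completeness is contractual.
    """
    K, k1 = p.K, p.k1
    n = R.total_length
    if n >= K:
        positions = np.arange(0, n - K + 1, k1, dtype=np.int64)
    else:
        positions = np.empty(0, dtype=np.int64)
    if bucket_bits is None:
        bucket_bits = default_bucket_bits(len(positions), p.mode)

    valid, bucket_ids = hash_positions(R, positions, K, bucket_bits)
    positions = positions[valid]
    bucket_ids = bucket_ids[valid]

    buckets: dict[int, np.ndarray] = {}
    if len(positions):
        order = np.argsort(bucket_ids, kind="stable")  # keeps positions ascending
        sb = bucket_ids[order]
        sp = positions[order]
        cut = np.flatnonzero(np.diff(sb)) + 1
        starts = np.concatenate(([0], cut, [len(sb)]))
        for a, b in zip(starts[:-1], starts[1:]):
            buckets[int(sb[a])] = sp[a:b].copy()
    return SeedIndex(
        bucket_bits=bucket_bits,
        K=K,
        k1=k1,
        n_positions=len(positions),
        buckets=buckets,
    )
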