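"""Seed-length and sampling-step selection.

Only reference positions that are multiples of k1 are indexed and only
query positions that are multiples of k2 are probed.  If gcd(k1, k2) = 1
and k1*k2 <= L - K + 1, every common substring of length >= L contains an
aligned position pair sampled on both sides with at least K characters
left (Chinese-remainder argument over the alignment shift), so no MEM of
length >= L is missed.

Given L, the seed length K comes from a threshold policy reproducing the
published configurations; (k1, k2) start from the classic "steps differ
by 1" rule (largest k with k*(k-1) <= L - K + 1, steps (k, k-1)) and k1
is then relaxed upward as far as the budget and coprimality allow.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

__all__ = [
    "MIN_L",
    "DEFAULT",
    "MEMORY_FRUGAL",
    "UnsupportedLengthError",
    "Params",
    "select_seed_length",
    "select_sampling_steps",
    "select_params",
]

#: Smallest supported minimum MEM length (K = 36 and a budget of >= 2).
MIN_L = 37

DEFAULT = "default"
MEMORY_FRUGAL = "mf"
_MODES = (DEFAULT, MEMORY_FRUGAL)

#: Seed length ceiling in memory-frugal mode.
_MF_SEED_CAP = 44


class UnsupportedLengthError(ValueError):
    pass


@dataclass(frozen=True)
class Params:
    """Seed/sampling configuration for one run."""

    L: int
    K: int
    k1: int
    k2: int
    mode: str = DEFAULT

    def __post_init__(self) -> None:
        if not (self.k1 >= self.k2 >= 1):
            raise ValueError(f"need k1 >= k2 >= 1, got ({self.k1}, {self.k2})")
        if gcd(self.k1, self.k2) != 1:
            raise ValueError(f"k1={self.k1} and k2={self.k2} are not coprime")
        if self.k1 * self.k2 > self.L - self.K + 1:
            raise ValueError(
                f"k1*k2 = {self.k1 * self.k2} exceeds budget "
                f"L-K+1 = {self.L - self.K + 1}"
            )
        if self.K > self.L:
            raise ValueError(f"seed length K={self.K} exceeds L={self.L}")
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def select_seed_length(L: int, mode: str = DEFAULT) -> int:
    """Seed length K for a minimum MEM length L.

    Thresholds: K = 36 below L = 80, K = 44 up to L = 200, K = 56 beyond;
    memory-frugal mode caps K at 44 (a shorter seed means a smaller packed
    key and hash table at the cost of more candidate verifications).
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if L < MIN_L:
        raise UnsupportedLengthError(
            f"minimum MEM length {L} is below the minimum supported value {MIN_L}"
        )
    if L < 80:
        K = 36
    elif L < 200:
        K = 44
    else:
        K = 56
    if mode == MEMORY_FRUGAL:
        K = min(K, _MF_SEED_CAP)
    return K


def select_sampling_steps(L: int, K: int) -> tuple[int, int]:
    """Sampling steps (k1, k2) for minimum MEM length L and seed length K.

    With budget B = L - K + 1: take the largest k with k*(k-1) <= B, set
    k2 = k - 1, then raise k1 to the largest j with j*k2 <= B and
    gcd(j, k2) = 1.  Since k = k2 + 1 is
    itself coprime with k2, the search always succeeds with k1 >= k.
    """
    B = L - K + 1
    if B < 2:
        raise ValueError(f"budget L-K+1 = {B} is below 2 (L={L}, K={K})")
    k = 2
    while (k + 1) * k <= B:
        k += 1
    k2 = k - 1
    k1 = B // k2
    while gcd(k1, k2) != 1:
        k1 -= 1
    assert k1 >= k
    return k1, k2


def select_params(L: int, mode: str = DEFAULT, seed_length: int | None = None) -> Params:
    """Full parameter selection from L (optionally overriding K)."""
    K = seed_length if seed_length is not None else select_seed_length(L, mode)
    if L < MIN_L:
        raise UnsupportedLengthError(
            f"minimum MEM length {L} is below the minimum supported value {MIN_L}"
        )
    k1, k2 = select_sampling_steps(L, K)
    return Params(L=L, K=K, k1=k1, k2=k2, mode=mode)
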