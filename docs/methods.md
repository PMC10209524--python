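# Methods

## Problem and model

Given two genomes R and Q over {A, C, G, T, N, other IUPAC}, report every
maximal exact match (MEM) of length ≥ L: a substring pair R[i..i+ℓ) =
Q[j..j+ℓ) of unambiguous nucleotides that cannot be extended on either
side. Ambiguity codes never match anything (not even themselves), so N
runs and the one-byte separator inserted between concatenated sequences
both terminate matches; per-sequence maximality therefore coincides with
maximality over the concatenated texts.

## Genome representation

Each multi-FASTA input is concatenated into a single uppercase byte
string with a single `>` byte between consecutive sequences and a table
of (name, absolute start, length) records. Internal coordinates are
0-based and absolute; output coordinates are 1-based and relative to the
containing sequence. Lowercase (soft-masked) input is uppercased and
treated as ordinary sequence; zero-length input sequences are dropped
with a warning because the predecessor structure samples at a step
bounded by the shortest sequence length.

## Parameter selection

For minimum MEM length L the seed length K follows a threshold policy —
36 for L < 80, 44 for 80 ≤ L < 200, 56 for L ≥ 200, capped at 44 in
memory-frugal mode — reconstructed from the documented configurations
((5,3,36) at L = 50, (7,5,44) at L = 80, (11,8,44) at L = 132,
(13,11,56) and (13,12,44) at L = 200). The thresholds 80 and 200 are the
simplest mapping consistent with all of those tuples; they are a policy,
not a law, and `--seed-len` overrides them. Sampling steps: with budget
B = L − K + 1, the base rule takes the largest k with k(k−1) ≤ B and
sets k2 = k − 1 (the classic "steps differ by one" choice); k1 is then
raised to the largest j with j·k2 ≤ B and gcd(j, k2) = 1. The package
supports L ≥ 37, the smallest L at which K = 36 leaves a budget of ≥ 2.

Correctness of sampling: for any alignment shift, the Chinese remainder
theorem gives a t in [0, k1·k2) with (i + t) ≡ 0 (mod k1) and
(j + t) ≡ 0 (mod k2); since k1·k2 ≤ L − K + 1, every common substring of
length ≥ L contains a sampled, indexed seed. The test suite verifies
this by exhaustive shift enumeration for every configuration in scope,
and end-to-end by comparing the engine against a brute-force oracle.

## Seed index

K-mers at reference positions ≡ 0 (mod k1) whose window is clean (all
A/C/G/T) are hashed into 2^b chained buckets. The hash is a fixed
splitmix64 finalizer over the 2-bit packing of the K-mer (packed values
up to 112 bits are folded to 64 by mixing the high word into the low
one); any well-dispersing deterministic function would serve, and this
one is fixed for cross-platform reproducibility. Table sizing: b =
min(2·⌈log2(#sampled positions)⌉, 26), minus 2 in memory-frugal mode.
Collisions are resolved by verification — every candidate is checked for
textual equality before extension — so bucket sizing affects only speed.
No bucket is ever capped; completeness is contractual.

## Scan, extension and the containment filter

Every query position ≡ 0 (mod k2) with a clean K-mer is probed.
Extension walks left and right while characters are equal and
unambiguous, using block-compared slices with a doubling window (64,
128, …) so long extensions cost O(length) byte comparisons in vectorized
chunks rather than per-character interpreter steps.

A per-diagonal cache stores the most recent extended run on each
diagonal d = r − q. A candidate seed (i, j) is skipped when the cached
run on diagonal i − j covers [j, j + K): the cached run matches along
its whole diagonal, so the seed's K-mer is guaranteed to match at i and
its extension would reproduce exactly that run. The skip is therefore
lossless, which the suite checks by comparing filter-on and filter-off
outputs. The cache records every extended run, including those below L —
a sub-L run still proves what a contained seed would re-derive. Cross-
diagonal containment is deliberately not used: a seed contained in a MEM
on a different diagonal can still start a distinct MEM. The cache is
scoped per (worker, query sequence) and is unbounded within that scope;
its size is bounded in practice by the number of distinct diagonals
touched.

Duplicates (one MEM reached from several sampled seeds) are allowed at
emission and removed by the collator.

## Predecessor structure

Output conversion needs, for each MEM start, the last sequence start ≤
that position. An array `Beg` with ⌈(|G| + 0.5)/step⌉ cells (equal to
⌊|G|/step⌋ + 1; the +0.5 keeps a guard cell) stores for cell c the last
record starting at or before c·step. Because step ≤ the shortest
sequence length, at most one sequence boundary falls inside a cell, so a
query reads Beg[pos // step] and checks at most one successor. The
production step is the largest power of two ≤ the shortest sequence
length, replacing the division with a shift; the generic builder accepts
any valid step so the structure is testable at non-power-of-two steps.
If the shortest sequence is so short that `Beg` would exceed 2^27 cells,
the map falls back to binary search with a warning — a pathological-
input guard, not a performance path. The same structure type serves the
query side when needed; the pipeline groups output by query record
directly, so only the reference map is consulted per MEM.

## Collation, sorting, spilling

Matches are ordered by query start then reference start, encoded as a
packed 80-bit key (40 bits per coordinate — genomes beyond 2^40 bases
are rejected with an explicit error). Blocks of up to `match_block`
triples (default 2^21; 2^19 in memory-frugal mode) are sorted and the
first 3/4 spilled to a per-(worker, query-sequence) temporary file, the
last 1/4 retained as overlap. Sorting uses a plain comparison sort at or
below 1024 items and otherwise an LSD radix pass over the top six bytes
of the key followed by a comparison sort inside equal-prefix runs; a
single radix implementation serves all block sizes here, with the
threshold exposed in `CollatorConfig` — selecting between radix variants
by cache size and thread count is hardware tuning outside this package's
scope. Spilling dedups against the stream tail; if a to-be-spilled key
precedes the last spilled key (overlap too small), a rescue re-reads the
sequence's spill, merges, re-sorts, dedups and rewrites — slower and
more memory-hungry, never lossy; each rescue logs a suggestion to raise
the block size. Final output is a streaming k-way merge of all spill
files per query sequence with cross-file deduplication.

Output format is the MUMmer/E-MEM-family convention: a `> name` header
per query sequence (also for sequences with zero matches), then one
tab-separated line per MEM with reference name, 1-based reference
position, 1-based query position and length.

## Parallel decomposition

The sampled probe positions are split into contiguous chunks, one per
worker, each with a private containment cache and collator. Because the
full concatenated texts are shared, extension is unrestricted and no
boundary overlap is needed — every sampled seed is probed by exactly one
worker. Chunks are currently processed sequentially (the worker count
shapes the decomposition and spill layout); the architectural contract —
byte-identical output for any worker count — is what the suite enforces,
and it is what makes swapping in a process pool safe later.

## Synthetic data and the oracle

The generator emulates the target regime at desk scale: multi-sequence
genomes of i.i.d. uniform ACGT bases and mutated near-copies with
per-base substitutions, short indels (lengths 1–5) and optional N runs —
the same-species, high-similarity scenario in which the containment
filter matters, plus divergent settings. It does not model biological
base composition, repeats, rearrangements or CNVs, so passing tests
demonstrate algorithmic correctness (completeness, soundness,
invariances), not performance on repeat-dense real genomes, where hash
buckets grow but the contracts are unchanged. Default test condition:
three sequences totalling 10 kb (6000/2500/1500 — the multi-sequence
layout exercises separators and the predecessor map), substitution rates
0–10 %, indel rate 5·10⁻⁴, three seeds, L ∈ {37, 50, 80, 132, 200};
sizes are set so the quadratic oracle stays fast.

The oracle enumerates every diagonal of the (R, Q) grid and reports
maximal runs of matching unambiguous characters of length ≥ L — exact,
duplicate-free, and independent of sampling, hashing and extension. It
is O(|R|·|Q|) and guarded at 2·10⁸ cell-equivalents; larger fixtures
would need a suffix-structure oracle, which is intentionally out of
scope. Since maximal runs do not depend on L (L only filters), grid
tests compute runs once per genome pair and filter per L.

## Numerical and degenerate-input choices

- Non-ACGT bytes never match, including self-matches; case is folded.
- Empty or all-N query sequences produce a header and no matches.
- `match_block` must be ≥ 8 and divisible by 4 so the 3/4 dump is exact.
- Ties: identical triples are duplicates (removed); distinct triples
  with equal (q, r) cannot arise, since the maximal run through a
  position pair is unique.
- All randomness in synthetic data flows from a single integer seed
  through `numpy.random.default_rng`; no global RNG state is used.

## Known limitations

- Forward-strand matches only (no reverse-complement), no MUM/MAM
  uniqueness classes, no approximate matching.
- The quadratic oracle bounds the size of fully verifiable fixtures.
- Worker execution is sequential; the speed benefit of real parallelism
  is not realized, only its output contract.
- The K-from-L thresholds are a reconstruction from documented
  configurations; other (K, L) mappings satisfying the sampling
  inequality would be equally correct and can be forced via
  `--seed-len`.
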