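# memfind

Find all **maximal exact matches (MEMs)** of length ≥ *L* between two
multi-FASTA genomes. A MEM is an exact substring match between the
reference *R* and the query *Q* that cannot be extended by a single
character on either side without hitting a mismatch, an ambiguity code,
or a sequence boundary. MEMs are the standard anchors for whole-genome
alignment, assembly seeding and referential compression; this package is
aimed at people who need the complete MEM set between two genomes —
including the hard case where the genomes are nearly identical.

## Method

`memfind` is a seed-and-extend finder built on **coprime sampling**:

- Reference *K*-mers at positions ≡ 0 (mod k1) go into a hash table;
  query positions ≡ 0 (mod k2) are probed against it.
- With gcd(k1, k2) = 1 and k1·k2 ≤ L − K + 1, every common substring of
  length ≥ L contains an aligned position pair sampled on both sides
  with at least K characters remaining (a Chinese-remainder argument
  over the alignment shift), so completeness is guaranteed while only a
  1/(k1·k2) fraction of the seed space is touched.
- *K* is chosen from *L* by a threshold policy (36 below L = 80, 44 up
  to L = 200, 56 beyond; capped at 44 in memory-frugal mode), then k2 is
  the largest k − 1 with k(k − 1) ≤ L − K + 1 and k1 is relaxed upward
  to the largest coprime value still inside the budget — e.g. L = 50
  gives (k1, k2, K) = (5, 3, 36), L = 80 gives (7, 5, 44), L = 200
  gives (13, 11, 56).
- Verified seeds are extended maximally in both directions; a
  **same-diagonal containment filter** skips any seed lying wholly
  inside an already-extended run on its diagonal (r − q), which makes
  near-identical genome pairs cheap without losing a single MEM.
- Output conversion from absolute to per-sequence coordinates uses a
  **sampled predecessor array**: one cell per `step` positions (step =
  largest power of two ≤ the shortest reference sequence length) holding
  the last sequence starting at or before the cell, so each lookup is a
  shift, one array read and at most one successor check.
- Matches are collated **block-wise**: each filled block is sorted
  (comparison sort for small blocks, an LSD-radix/comparison hybrid over
  the packed (q, r) key for large ones), its first 3/4 spilled to a
  temporary file and the last 1/4 retained as overlap; an out-of-order
  spill triggers a lossless rescue re-sort. Spill streams are k-way
  merged with deduplication into the final text output.

Worker count, memory-frugal mode, match-block size and the containment
filter are resource knobs only: the output is byte-identical under all
of them.

## Worked example

```
$ memfind fixtures fx --lengths 3000,1200 --divergence 0.01 --seed 7
wrote fx/ref.fa and fx/query.fa
$ memfind fx/ref.fa fx/query.fa -o out.mems -l 50
sequences ref/query: 2/2  seeds probed: 1376  candidates verified: 31  MEMs written: 30  rescues: 0
$ head -8 out.mems
> seq1
 seq1	84	84	186
 seq1	271	271	238
 seq1	531	531	63
 seq1	595	595	60
 seq1	656	656	88
 seq1	745	745	79
 seq1	825	825	135
```

The fixture is a two-sequence 4.2 kb genome and a 1 %-diverged copy of
it. Of the 1376 sampled query positions only 31 candidate seeds survived
the containment filter and hash verification, yielding 30 MEMs of length
≥ 50. Each output block starts with a `> name` header for one query
sequence (emitted even when it has no matches) followed by one line per
MEM: reference sequence name, 1-based start in that reference sequence,
1-based start in the query sequence, and match length — so the first
line reports a 186 bp exact match starting at position 84 of `seq1` in
both genomes, i.e. the first stretch unbroken by a substitution.

Useful flags: `-t N` (workers), `-mf` (memory-frugal), `--seed-len K`,
`--match-block B`, `--temp-dir D`, `--keep-temp`, `--no-containment`,
`--verbose`. The same machinery is available as a library
(`memfind.run_pipeline`, `memfind.oracle_mems`, …).

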