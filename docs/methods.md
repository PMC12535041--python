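# Methods

## The problem

A suffix array (SA) of a text `T` of length `n` is the permutation of
`0..n-1` that lists the start positions of all suffixes in lexicographic
order; binary search over it finds every occurrence of a pattern of length
`m` in `O(m log n)`. For large sequence databases the SA itself (one
machine word per text position) dominates memory. A **sparse suffix array
(SSA)** with sparseness factor `k` keeps only the suffixes starting at
positions divisible by `k` — `⌈n/k⌉` entries — trading a factor-k memory
saving against slower queries.

The traditional way to build an SSA is to build the full SA and discard
all entries not divisible by k, so *peak* memory during construction is
unchanged. This package builds the SSA directly.

## The text transformation

1. Assign each distinct character an unsigned code in `1..σ`, in ascending
   character order, using `b = ⌈log2(σ+1)⌉` bits. Code 0 is reserved as a
   sentinel that sorts below every real character (the 20-letter amino-acid
   alphabet therefore needs 5 bits per character, sentinel included).
2. Split the text into consecutive non-overlapping k-mers and bit-pack each
   one into a single unsigned integer, leftmost character in the most
   significant bits, stored in the smallest standard word (8/16/32/64 bits)
   that holds `b·k` bits. For amino acids at `k = 3` this is 15 bits in a
   16-bit word.

Because codes are assigned in lexicographic order and packing puts earlier
characters in higher bits, integer comparison of packed blocks equals
lexicographic comparison of k-mers. Suffixes of the packed sequence
therefore sort exactly like the text suffixes at positions `0, k, 2k, …`:
the suffix array of the packed sequence, multiplied by k, **is** the SSA.
The packed sequence has `~n/k` elements, so both the sorter input and the
produced array shrink by a factor k; the price is that the transformed
alphabet grows from `σ` to the packed code space `2^(b·k)` (up to `σ^k`
distinct values), which inflates the per-character bucket arrays of the
induced-sorting stage. Peak construction memory falls with k until that
bucket term dominates, then rises again — this non-monotone trend is the
method's characteristic trade-off and is measured by
`construction_footprint`.

### Tail handling

The text length need not be a multiple of k. One sentinel is conceptually
appended after the text and the sequence is right-padded with further
sentinels so that the packed sequence always ends in exactly **one**
all-zero block (`⌈n/k⌉ + 1` blocks in total). This choice, which the
packing has to make on its own, guarantees two things at once: the sorter's
unique-minimum-terminator precondition holds, and a padded tail block
compares strictly below any block containing a real character, so the
order-preservation property extends through the last block. Packed
positions that map at or beyond `n` (the terminator region) are filtered
out of the SSA positionally.

## Suffix sorting

Sorting uses SA-IS (induced sorting): suffixes are classified L/S, the
leftmost-S (LMS) suffixes are sorted — recursively on a reduced string when
their substrings are not all distinct, with each recursion level at most
half the parent's length — and the remaining order is induced in two
linear bucket scans. Bucket arrays are allocated dense, sized by the packed
alphabet bound `2^(b·k)`, which is what makes the bucket memory term real
and measurable. Above a dense-bucket limit of `2^24` the packed code space
is far sparser than the sequence is long, so block values are first
rank-compacted (an order-preserving relabelling via sorted unique values)
and the sort proceeds on the compact alphabet; correctness is unaffected.
The inner loops are JIT-compiled with numba; a 10 Mb nucleotide text sorts
in a few seconds. A brute-force comparison sort (`naive_suffix_array`)
serves as the independent oracle in the tests and is never used on the
construction path.

## Divisor strategy

For large k the packed word overflows 64 bits or the bucket space becomes
the dominant cost. `build_with_divisor(text, k, d)` builds the SSA at a
divisor `d` of `k` and subsamples the result to positions divisible by k.
Since the d-sparse SSA contains every multiple of k in the correct relative
order, the result is identical to direct construction at k.

## Searching the SSA

An occurrence of a pattern `P` (length `m ≥ k`) at position `p` need not
start at a sampled position, but the next sampled position `q = p + s`,
`s = (-p) mod k < k ≤ m`, lies inside the occurrence. The search therefore
runs one binary-searched range query per shift `s ∈ 0..k-1` for the
pattern suffix `P[s:]` and verifies the skipped s-character prefix directly
against the text (the suffix part is already certified by the binary
search, so only `s` characters are probed). Each occurrence is found by
exactly one shift, so the union over shifts needs no deduplication, and a
query costs exactly `min(k, m)` binary searches.

Patterns with `m < k` can fall entirely between sampled positions, so they
are rejected by default; an explicit `scan_short` option falls back to a
direct text scan for them. Matches may span the separator character used
to concatenate FASTA records; the CLI's `--reject-spanning` flag drops
such matches when the caller considers records independent.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `k` | sparseness factor (sampling stride, k-mer width) | required | memory/speed trade-off; pick `k·σ` near ~20 as a starting point for a new dataset |
| `max_symbols` | distinct-character cap for an alphabet | 64 | keeps `b ≤ 6`; covers nucleotide, ambiguity-code and amino-acid alphabets with a separator |
| `d` | construction divisor of `k` | `None` (direct) | escape hatch when `b·k > 64` or `2^(b·k)` buckets would dominate |
| `separator` | FASTA concatenation character | `-` | the convention used for concatenated protein databases |
| `DENSE_BUCKET_LIMIT` | largest dense bucket allocation | `2^24` | 128 MB of int64 buckets; beyond this rank compaction is always cheaper |

Case is significant ('a' ≠ 'A'); character order is native byte order, so
whether the separator sorts before or after the sequence letters is decided
by its byte value. No case folding or IUPAC equivalence is applied.

## Memory accounting

`construction_footprint(text, k)` runs both construction routes with an
allocation ledger attached and reports the peak number of live array
*words* (one word per array element): encoded text, sorter input, suffix
array, type arrays and bucket arrays across all recursion levels. This is
an architecture-independent proxy for peak resident memory — it ignores
dtype width (the packed input is deliberately stored in narrow words, so
the byte-level saving of the direct route is, if anything, understated)
and ignores constant-size overheads. On a 10 Mb uniform 4-letter text the
direct route's peak is ~53% below the sampled route's at `k = 3`, bottoms
out around `k = 6`, and rises again by `k = 8` when the `2^(b·k)` bucket
term (b = 3 bits for a 4-letter alphabet) takes over — the same qualitative
shape the memory model predicts.

## Synthetic data

`generate_synthetic` draws i.i.d. uniform characters. Real genomes and
protein databases are repetitive, skewed in composition and structured;
uniform text is the *hardest* case for SA-IS recursion depth arguments but
says nothing about compressibility-dependent behaviour. Passing tests on
synthetic text therefore demonstrate correctness of the construction and
search algebra (which is input-independent and additionally verified
exhaustively on small texts), not wall-clock performance on real data.

## Numerical and design choices

- Positions are 0-based throughout; ranges are half-open.
- `word_bits` is restricted to {8, 16, 32, 64}; `b·k > 64` is refused with
  a pointer to the divisor strategy.
- The index format (magic `SSAX`, version, k, n, alphabet, positions as
  little-endian u64, CRC32 trailer) is fixed little-endian for portability;
  truncation, foreign files, version mismatch and corruption are reported
  as distinct errors.
- `build_sampled` drops the sentinel suffix before sampling so both
  construction routes are sentinel-agnostic in their output.
- Ties cannot arise in suffix comparisons: suffixes have distinct lengths
  and the terminator is a unique minimum.

## Known limitations

- Single-byte alphabets only (≤ 64 distinct symbols); no Unicode collation.
- No ISA/LCP construction, maximal-exact-match finding or approximate
  matching; the index supports exact occurrence queries.
- Bucket arrays are dense per call below the compaction limit; a sparse or
  hashed bucket scheme could push the feasible k higher and is future work.
- Word-count instrumentation is a proxy; it does not model allocator
  behaviour or the narrower dtypes of the packed input.
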