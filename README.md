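# sparsesa

Direct construction of **sparse suffix arrays** (SSAs) for nucleotide and
protein sequence data — without ever building the full suffix array — plus
exact pattern search over the sparse index.

A sparse suffix array with sparseness factor *k* indexes only the suffixes
starting at positions divisible by *k*: `⌈n/k⌉` entries instead of *n*.
It is the lightweight index behind peptide lookup against large protein
databases and seeding in comparative genomics, but the usual way to build
one — construct the full suffix array, keep every k-th entry — needs as
much peak memory as the full index.

`sparsesa` instead applies an order-preserving transformation first: each
character gets a minimal-width integer code in lexicographic order (5 bits
for the 20 amino acids, sentinel included), and each non-overlapping k-mer
is bit-packed into one machine word, leftmost character in the most
significant bits (15 bits → a 16-bit word for amino-acid 3-mers). Integer
order of packed blocks equals lexicographic order of k-mers, so the suffix
array of the packed sequence — built here with an SA-IS induced-sorting
implementation over integer alphabets — multiplied by *k* **is** the SSA.
Both the sorter input and its output shrink by a factor *k*; the cost is
bucket memory growing with the packed alphabet `2^(b·k)`, so the sweet
spot sits at moderate *k* (rule of thumb: `k·σ` near 20). For larger *k*,
build at a divisor *d* of *k* and subsample (`build_with_divisor`).

Queries run *k* shifted binary searches (one per alignment of the pattern
to the sampling grid) with in-text verification of the skipped prefix, and
return exactly the occurrences a full-text scan would.

## Worked example

```python
>>> import sparsesa as s
>>> ssa = s.build_direct("banana", k=2)
>>> list(ssa.positions)
[0, 4, 2]
```

The three sampled suffixes `banana` (0), `nana` (2) and `na` (4) appear in
lexicographic order `banana < na < nana` — positions `[0, 4, 2]` — and
there are `⌈6/2⌉ = 3` of them. The same array falls out of full-SA
construction plus sampling:

```python
>>> s.build_sampled("banana", 2) == ssa
True
>>> list(s.find_all(ssa, "banana", "ana"))
[1, 3]
```

Neither occurrence of `ana` starts at a sampled position; both are found
through the shift-1 query for `na` (sampled positions 2 and 4) plus a
one-character check of the skipped `a`.

The same thing from the shell, on FASTA input (records are concatenated
with `-`, the convention for protein databases):

```sh
$ sparsesa build --input seqs.fa --sparseness 3 --output seqs.ssax
$ sparsesa query --index seqs.ssax --input seqs.fa --pattern ANA
ANA	127	rec4
$ sparsesa verify --input seqs.fa --sparseness 3
OK: direct == sampled (134 entries, k=3)
```

Peak construction memory can be compared between the two routes directly:

```python
>>> text = s.generate_synthetic("ACGT", 10_000_000, seed=42)
>>> fp = s.construction_footprint(text, 3)
>>> round(fp.reduction, 3)
0.534
```

i.e. on a 10 Mb nucleotide text the direct route's peak working set
(sorter input + suffix array + induced-sorting bucket arrays, counted in
words) is 53% smaller than full-construction-plus-sampling at `k = 3`.

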