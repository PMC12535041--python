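"""Sparse suffix array construction: direct, sampled, and divisor paths.

A sparse suffix array (SSA) with sparseness factor k keeps only the
suffixes starting at positions divisible by k — ``ceil(n/k)`` entries
instead of n. Three construction routes are provided:

``build_direct``
    The packing route: encode the text, pack non-overlapping k-mers into
    single integers (order-preserving), suffix-sort the packed sequence,
    and map packed positions back by multiplying by k. The full suffix
    array is never materialised, so the peak working set shrinks with k
    until the ``2**(b*k)`` bucket term takes over.

``build_sampled``
    The traditional baseline: build the full suffix array and keep every
    entry divisible by k. Peak memory equals full-SA construction.

``build_with_divisor``
    For large k the packed word or bucket space overflows; build at a
    divisor d of k instead and subsample the result to stride k.

The two routes are provably equivalent entry-for-entry, which the
test-suite checks exhaustively on small texts and by randomized sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import Alphabet, build_alphabet, encode_text
from .errors import PackingError, SparseSAError
from .packing import pack, packed_alphabet_size
from .sais import AllocationLedger, sais


@dataclass(frozen=True)
class SparseSuffixArray:
    """Sampled suffix positions of a text, in lexicographic suffix order.

    Every position is divisible by ``k`` and there are exactly
    ``ceil(n/k)`` of them.
    """

    positions: np.ndarray
    k: int
    n: int
    alphabet: Alphabet

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SparseSuffixArray)
            and self.k == other.k
            and self.n == other.n
            and self.alphabet == other.alphabet
            and np.array_equal(self.positions, other.positions)
        )


def _validate(text: str, k: int) -> None:
    if len(text) == 0:
        raise SparseSAError("empty input")
    if k < 1:
        raise SparseSAError(f"sparseness factor must be >= 1, got {k}")


def build_direct(
    text: str,
    k: int,
    alphabet: Alphabet | None = None,
    ledger: AllocationLedger | None = None,
) -> SparseSuffixArray:
    """Build the SSA directly via the k-mer packing transformation.

    Equivalent, entry for entry, to :func:`build_sampled` — but the full
    suffix array of the text is never constructed.
    """
    _validate(text, k)
    if alphabet is None:
        alphabet = build_alphabet(text)
    encoded = encode_text(text, alphabet)
    if alphabet.bits_per_symbol * k > 64:
        raise PackingError(
            f"packing {k} symbols of {alphabet.bits_per_symbol} bits exceeds "
            "64 bits; reduce k or use build_with_divisor"
        )
    packed = pack(encoded, k)
    if ledger is not None:
        ledger.add(encoded.n + packed.blocks.size)  # codes + packed input
    sa = sais(packed.blocks, packed_alphabet_size(alphabet, k), ledger)
    positions = sa.order * k
    positions = positions[positions < encoded.n]
    if ledger is not None:
        ledger.remove(encoded.n + packed.blocks.size)
    return SparseSuffixArray(positions=positions, k=k, n=encoded.n, alphabet=alphabet)


def build_sampled(
    text: str,
    k: int,
    alphabet: Alphabet | None = None,
    ledger: AllocationLedger | None = None,
) -> SparseSuffixArray:
    """Build the SSA the traditional way: full suffix array, then sampling.

    The full suffix array of the text (with a sentinel terminator, whose
    entry is dropped) is filtered to positions divisible by k, keeping
    their order.
    """
    _validate(text, k)
    if alphabet is None:
        alphabet = build_alphabet(text)
    encoded = encode_text(text, alphabet)
    seq = np.zeros(encoded.n + 1, dtype=np.int64)
    seq[: encoded.n] = encoded.codes
    if ledger is not None:
        ledger.add(encoded.n + seq.size)
    sa = sais(seq, alphabet.size + 1, ledger)
    positions = sa.order[sa.order < encoded.n]  # drop the sentinel entry
    positions = positions[positions % k == 0]
    if ledger is not None:
        ledger.remove(encoded.n + seq.size)
    return SparseSuffixArray(positions=positions, k=k, n=encoded.n, alphabet=alphabet)


def build_with_divisor(
    text: str,
    k: int,
    d: int,
    alphabet: Alphabet | None = None,
) -> SparseSuffixArray:
    """Build at sparseness d (a divisor of k), then subsample to stride k.

    The escape hatch for large k: packing at d keeps the word width and the
    transformed alphabet manageable, and subsampling the d-sparse result to
    positions divisible by k yields exactly ``build_direct(text, k)``.
    """
    _validate(text, k)
    if d < 1 or k % d != 0:
        raise SparseSAError(f"d must divide k (got k={k}, d={d})")
    ssa_d = build_direct(text, d, alphabet=alphabet)
    positions = ssa_d.positions[ssa_d.positions % k == 0]
    return SparseSuffixArray(
        positions=positions, k=k, n=ssa_d.n, alphabet=ssa_d.alphabet
    )


@dataclass(frozen=True)
class ConstructionFootprint:
    """Peak working set, in words, of both construction routes on one text.

    Words count array elements of the encoded text, the sorter input, the
    suffix array, type arrays and bucket arrays over all recursion levels —
    the terms that dominate induced sorting's memory.
    """

    k: int
    n: int
    packed_length: int
    direct_peak_words: int
    sampled_peak_words: int

    @property
    def reduction(self) -> float:
        """Fractional peak-memory reduction of the direct route (1 - direct/sampled)."""
        return 1.0 - self.direct_peak_words / self.sampled_peak_words


def construction_footprint(text: str, k: int) -> ConstructionFootprint:
    """Measure the peak allocation of the direct and sampled routes.

    Runs both constructions with an :class:`AllocationLedger` attached and
    verifies on the way that the two outputs agree.
    """
    alphabet = build_alphabet(text)
    direct_ledger = AllocationLedger()
    sampled_ledger = AllocationLedger()
    direct = build_direct(text, k, alphabet=alphabet, ledger=direct_ledger)
    sampled = build_sampled(text, k, alphabet=alphabet, ledger=sampled_ledger)
    if direct != sampled:
        raise SparseSAError("construction routes disagree")  # pragma: no cover
    packed_length = -(-len(text) // k) + 1
    return ConstructionFootprint(
        k=k,
        n=len(text),
        packed_length=packed_length,
        direct_peak_words=direct_ledger.peak,
        sampled_peak_words=sampled_ledger.peak,
    )
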