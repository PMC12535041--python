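"""Order-preserving k-mer bit-packing.

The text transformation at the heart of direct sparse-suffix-array
construction: consecutive non-overlapping k-mers of the encoded text are
each packed into one unsigned machine word, leftmost character in the most
significant bits. Because character codes are assigned in lexicographic
order and the sentinel code 0 is smaller than every real code, integer
comparison of packed blocks reproduces lexicographic comparison of the
underlying k-mers — so the suffix order of the packed sequence equals the
suffix order of the original text restricted to positions divisible by k.

Tail handling: one sentinel is conceptually appended after the text and the
sequence is right-padded with further sentinels so that the packed sequence
always ends in exactly one all-zero block. That block is the unique minimum
the induced-sorting stage requires, and padded tails compare smaller than
any real suffix. The packed length is therefore always ``ceil(n/k) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import Alphabet, EncodedText
from .errors import PackingError

_WORD_SIZES = (8, 16, 32, 64)
_DTYPES = {8: np.uint8, 16: np.uint16, 32: np.uint32, 64: np.uint64}


def _word_bits_for(total_bits: int) -> int:
    for w in _WORD_SIZES:
        if w >= total_bits:
            return w
    raise PackingError(
        "packed k-mer exceeds 64 bits; reduce k or use build_with_divisor"
    )


@dataclass(frozen=True)
class PackedText:
    """The transformed text: packed k-mer blocks plus packing metadata.

    ``blocks`` is stored in the smallest standard unsigned dtype that holds
    ``bits_per_symbol * k`` bits (the memory saving the transformation is
    for). The final block is always 0, the unique all-sentinel terminator.
    """

    blocks: np.ndarray
    k: int
    bits_per_symbol: int
    word_bits: int
    source_n: int

    @property
    def alphabet_upper_bound(self) -> int:
        """Exclusive upper bound on block values: 2**(b*k)."""
        return 1 << (self.bits_per_symbol * self.k)


def pack(encoded: EncodedText, k: int) -> PackedText:
    """Pack non-overlapping k-mers of *encoded* into single integers.

    Block ``j`` equals ``sum(code[j*k + i] << (b*(k-1-i)) for i in 0..k-1)``
    with out-of-range positions contributing the sentinel code 0.

    Raises
    ------
    PackingError
        If ``bits_per_symbol * k > 64``.
    """
    if k < 1:
        raise PackingError(f"sparseness factor must be >= 1, got {k}")
    b = encoded.alphabet.bits_per_symbol
    total_bits = b * k
    word_bits = _word_bits_for(total_bits)

    n = encoded.n
    n_blocks = -(-n // k) + 1  # ceil(n/k) real-character blocks + terminator
    padded = np.zeros(n_blocks * k, dtype=np.uint64)
    padded[:n] = encoded.codes
    shifts = np.array([b * (k - 1 - i) for i in range(k)], dtype=np.uint64)
    blocks = (padded.reshape(n_blocks, k) << shifts).sum(
        axis=1, dtype=np.uint64
    )
    return PackedText(
        blocks=blocks.astype(_DTYPES[word_bits]),
        k=k,
        bits_per_symbol=b,
        word_bits=word_bits,
        source_n=n,
    )


def packed_alphabet_size(alphabet: Alphabet, k: int) -> int:
    """Size of the transformed alphabet, ``2**(b*k)``.

    This is the exclusive upper bound on packed block values and the
    bucket-count driver for induced sorting: the transformed alphabet grows
    from sigma to (up to) sigma**k distinct k-mers, and buckets are indexed
    by the packed code space 2**(b*k).
    """
    if k < 1:
        raise PackingError(f"sparseness factor must be >= 1, got {k}")
    total_bits = alphabet.bits_per_symbol * k
    _word_bits_for(total_bits)  # raises if > 64
    return 1 << total_bits
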