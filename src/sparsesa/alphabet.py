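"""Order-preserving minimal-bit character encoding.

Every distinct character of the input text is assigned an unsigned integer
code such that code order equals the native (byte/ordinal) order of the
characters. Code 0 is reserved as a sentinel: it is never produced for a
real character, so sentinel-padded blocks compare strictly smaller than any
block containing text. With the sentinel included, ``sigma`` real symbols
need ``bits_per_symbol = ceil(log2(sigma + 1))`` bits each — e.g. the
20-letter amino-acid alphabet needs 5 bits per character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError

#: Default cap on distinct symbols; keeps packed alphabets manageable.
MAX_SYMBOLS = 64

SENTINEL_CODE = 0


@dataclass(frozen=True)
class Alphabet:
    """An order-preserving mapping from characters to codes ``1..sigma``.

    Attributes
    ----------
    symbols : str
        The distinct characters in ascending native order; ``symbols[i]``
        has code ``i + 1``.
    """

    symbols: str
    code_of: dict[str, int] = field(repr=False)
    bits_per_symbol: int
    sentinel_code: int = SENTINEL_CODE

    @property
    def size(self) -> int:
        """Number of real symbols (sigma); codes run 1..size."""
        return len(self.symbols)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self.symbols == other.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)

    def _lookup_table(self) -> np.ndarray:
        """256-entry ord -> code table; 0 marks characters outside the alphabet."""
        lut = np.zeros(256, dtype=np.uint8)
        for ch, code in self.code_of.items():
            lut[ord(ch)] = code
        return lut


@dataclass(frozen=True)
class EncodedText:
    """The text as a sequence of codes in ``1..sigma``, plus its length."""

    codes: np.ndarray
    n: int
    alphabet: Alphabet


def build_alphabet(text: str, max_symbols: int = MAX_SYMBOLS) -> Alphabet:
    """Build the minimal-bit, order-preserving alphabet of *text*.

    Codes 1..sigma are assigned in ascending character order, so integer
    comparison of codes reproduces lexicographic comparison of characters.
    Code 0 stays reserved for the sentinel.

    Raises
    ------
    AlphabetError
        If *text* is empty, contains more than *max_symbols* distinct
        characters, or contains characters outside the single-byte range.
    """
    if len(text) == 0:
        raise AlphabetError("empty input")
    symbols = sorted(set(text))
    if len(symbols) > max_symbols:
        raise AlphabetError(
            f"{len(symbols)} distinct symbols exceed the limit of {max_symbols}"
        )
    if ord(symbols[-1]) > 255:
        raise AlphabetError(
            f"character {symbols[-1]!r} is outside the single-byte range"
        )
    sigma = len(symbols)
    bits = sigma.bit_length()  # smallest b with 2**b >= sigma + 1
    code_of = {ch: i + 1 for i, ch in enumerate(symbols)}
    return Alphabet(symbols="".join(symbols), code_of=code_of, bits_per_symbol=bits)


def encode_text(text: str, alphabet: Alphabet) -> EncodedText:
    """Map *text* character-wise to its integer codes.

    Raises
    ------
    AlphabetError
        If a character of *text* is not in *alphabet*; the message names the
        character and its position.
    """
    try:
        raw = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise AlphabetError(
            f"character {text[exc.start]!r} at position {exc.start} "
            "is not in the alphabet"
        ) from exc
    codes = alphabet._lookup_table()[raw]
    if codes.size and codes.min() == SENTINEL_CODE:
        pos = int(np.argmin(codes != SENTINEL_CODE))
        raise AlphabetError(
            f"character {text[pos]!r} at position {pos} is not in the alphabet"
        )
    return EncodedText(codes=codes, n=len(text), alphabet=alphabet)


def decode_text(encoded: EncodedText) -> str:
    """Inverse of :func:`encode_text` (roundtrip identity)."""
    symbols = encoded.alphabet.symbols
    return "".join(symbols[c - 1] for c in encoded.codes)
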