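"""FASTA concatenation, binary index serialization and synthetic texts.

Multi-record FASTA input is concatenated into a single searchable text
with one separator character between consecutive records (the convention
used for protein databases, where a dash joins the entries); separator
positions are kept so a match position can be mapped back to its record.

The on-disk index format ("SSAX") stores the sparseness factor, text
length, alphabet and positions; little-endian throughout, with a CRC32
trailer so truncation and corruption are detected on load.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from os import PathLike
from typing import IO, Iterator

import numpy as np

from .alphabet import Alphabet, build_alphabet
from .errors import FastaError, IndexFormatError
from .ssa import SparseSuffixArray

_MAGIC = b"SSAX"
_VERSION = 1
_HEADER = struct.Struct("<4sBBIQH")  # magic, version, word size, k, n, sigma


@dataclass(frozen=True)
class ConcatenatedText:
    """Record sequences joined with a separator, plus boundary bookkeeping."""

    text: str
    boundaries: np.ndarray
    separator: str
    record_ids: tuple[str, ...]

    def record_at(self, position: int) -> str:
        """Id of the record covering *position* (separators belong to neither;
        the preceding record is reported)."""
        i = int(np.searchsorted(self.boundaries, position, side="right"))
        return self.record_ids[i]


def _parse_fasta(lines: Iterator[str]) -> Iterator[tuple[str, str, int]]:
    """Yield (record id, sequence, starting line number) triples."""
    rec_id: str | None = None
    chunks: list[str] = []
    rec_line = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith(">"):
            if rec_id is not None:
                yield rec_id, "".join(chunks), rec_line
            rec_id = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
            rec_line = lineno
        else:
            if rec_id is None:
                raise FastaError(
                    f"line {lineno}: sequence data before any '>' header"
                )
            chunks.append(line)
    if rec_id is not None:
        yield rec_id, "".join(chunks), rec_line
    else:
        raise FastaError("no FASTA records found")


def read_and_concatenate(
    fasta_source: str | PathLike[str] | IO[str],
    separator: str = "-",
) -> ConcatenatedText:
    """Read FASTA records and join them with *separator* between records.

    No leading or trailing separator is added. Raises :class:`FastaError`
    on malformed input (with the line number) or when a record's sequence
    contains the separator (with the record id).
    """
    if len(separator) != 1:
        raise FastaError("separator must be a single character")
    if hasattr(fasta_source, "read"):
        records = list(_parse_fasta(iter(fasta_source)))
    else:
        with open(fasta_source) as handle:
            records = list(_parse_fasta(iter(handle)))
    pieces: list[str] = []
    ids: list[str] = []
    boundaries: list[int] = []
    offset = 0
    for rec_id, seq, rec_line in records:
        if not seq:
            raise FastaError(f"line {rec_line}: record {rec_id!r} has an empty sequence")
        if separator in seq:
            raise FastaError(
                f"record {rec_id!r} contains the separator character {separator!r}"
            )
        if pieces:
            boundaries.append(offset)
            offset += 1
        pieces.append(seq)
        ids.append(rec_id)
        offset += len(seq)
    return ConcatenatedText(
        text=separator.join(pieces),
        boundaries=np.array(boundaries, dtype=np.int64),
        separator=separator,
        record_ids=tuple(ids),
    )


def read_text(source: str | PathLike[str]) -> ConcatenatedText:
    """Read a plain-text file as a single record (whitespace stripped at ends)."""
    with open(source) as handle:
        text = handle.read().strip()
    return ConcatenatedText(
        text=text,
        boundaries=np.array([], dtype=np.int64),
        separator="",
        record_ids=("text",),
    )


def save_index(ssa: SparseSuffixArray, sink: str | PathLike[str] | IO[bytes]) -> None:
    """Serialize an SSA to the binary SSAX format."""
    payload = _HEADER.pack(
        _MAGIC, _VERSION, 64, ssa.k, ssa.n, ssa.alphabet.size
    )
    payload += ssa.alphabet.symbols.encode("latin-1")
    payload += np.asarray(ssa.positions, dtype="<u8").tobytes()
    blob = payload + struct.pack("<I", zlib.crc32(payload))
    if hasattr(sink, "write"):
        sink.write(blob)
    else:
        with open(sink, "wb") as handle:
            handle.write(blob)


def load_index(source: str | PathLike[str] | IO[bytes]) -> SparseSuffixArray:
    """Load an SSA from the binary SSAX format.

    Raises :class:`IndexFormatError` with distinct messages for foreign
    magic bytes, unsupported versions, truncation and checksum mismatch.
    """
    if hasattr(source, "read"):
        blob = source.read()
    else:
        with open(source, "rb") as handle:
            blob = handle.read()
    if len(blob) < _HEADER.size + 4:
        raise IndexFormatError("unexpected end of index")
    if blob[:4] != _MAGIC:
        raise IndexFormatError("not a sparsesa index")
    magic, version, _word, k, n, sigma = _HEADER.unpack(blob[: _HEADER.size])
    if version != _VERSION:
        raise IndexFormatError(f"unsupported index version {version}")
    n_positions = -(-n // k)
    expected = _HEADER.size + sigma + 8 * n_positions + 4
    if len(blob) < expected:
        raise IndexFormatError("unexpected end of index")
    payload, (crc,) = blob[:-4], struct.unpack("<I", blob[-4:])
    if zlib.crc32(payload) != crc:
        raise IndexFormatError("index checksum mismatch")
    symbols = blob[_HEADER.size : _HEADER.size + sigma].decode("latin-1")
    alphabet = build_alphabet(symbols)
    positions = np.frombuffer(
        blob, dtype="<u8", count=n_positions, offset=_HEADER.size + sigma
    ).astype(np.int64)
    return SparseSuffixArray(positions=positions, k=k, n=n, alphabet=alphabet)


def generate_synthetic(alphabet: str, length: int, seed: int) -> str:
    """I.i.d. uniform random text over *alphabet*; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    rng = np.random.default_rng(seed)
    symbols = np.frombuffer(alphabet.encode("latin-1"), dtype=np.uint8)
    draws = symbols[rng.integers(0, len(symbols), size=length)]
    return draws.tobytes().decode("latin-1")
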