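"""Exact pattern matching over a sparse suffix array.

Because only every k-th suffix is indexed, a pattern occurrence at
position p is reachable only through the sampled suffix at the next
sampled position at or after p. The search therefore runs k shifted
queries: for each shift s in 0..k-1 it binary-searches the pattern suffix
``pattern[s:]`` in the SSA, and every hit q yields the candidate start
``p = q - s``, accepted after verifying the skipped s-character prefix
directly against the text. Each occurrence is discovered by exactly one
shift (s = -p mod k), so the union over shifts needs no deduplication.

Patterns shorter than k are rejected by default: an occurrence may contain
no sampled position at all, making the shifted-query scheme incomplete
there. Pass ``scan_short=True`` to fall back to a direct text scan for
such patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SearchError
from .ssa import SparseSuffixArray


@dataclass(frozen=True)
class MatchSet:
    """Sorted, duplicate-free start positions of a pattern in the text."""

    occurrences: np.ndarray

    def __len__(self) -> int:
        return len(self.occurrences)

    def __iter__(self):
        return iter(int(p) for p in self.occurrences)

    def __contains__(self, p) -> bool:
        i = int(np.searchsorted(self.occurrences, p))
        return i < len(self.occurrences) and self.occurrences[i] == p


def suffix_range(
    ssa: SparseSuffixArray, text: str, query: str
) -> tuple[int, int]:
    """Half-open range ``[lo, hi)`` of SSA entries whose suffix starts with *query*.

    Binary search over the lexicographically ordered sampled suffixes;
    comparisons read the original text character-wise. Empty range when no
    sampled suffix has *query* as a prefix.
    """
    if not query:
        raise SearchError("empty query")
    positions = ssa.positions
    m = len(query)

    # leftmost index whose suffix is >= query
    lo, hi = 0, len(positions)
    while lo < hi:
        mid = (lo + hi) // 2
        p = int(positions[mid])
        if text[p : p + m] < query:
            lo = mid + 1
        else:
            hi = mid
    start = lo

    # leftmost index whose suffix is > query and does not start with it
    lo, hi = start, len(positions)
    while lo < hi:
        mid = (lo + hi) // 2
        p = int(positions[mid])
        if text[p : p + m] <= query:
            lo = mid + 1
        else:
            hi = mid
    return start, lo


def _scan(text: str, pattern: str) -> np.ndarray:
    hits = []
    i = text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return np.array(hits, dtype=np.int64)


def find_all(
    ssa: SparseSuffixArray,
    text: str,
    pattern: str,
    scan_short: bool = False,
) -> MatchSet:
    """All occurrences of *pattern* in *text*, via k shifted SSA queries.

    Raises
    ------
    SearchError
        If the pattern is empty, or shorter than the sparseness factor
        while *scan_short* is disabled.
    """
    m = len(pattern)
    if m == 0:
        raise SearchError("empty pattern")
    k = ssa.k
    if m < k:
        if not scan_short:
            raise SearchError(
                f"pattern shorter than sparseness factor ({m} < {k}); "
                "enable the scan fallback for sub-k patterns"
            )
        return MatchSet(occurrences=_scan(text, pattern))

    found: list[int] = []
    for s in range(k):
        lo, hi = suffix_range(ssa, text, pattern[s:])
        for q in ssa.positions[lo:hi]:
            p = int(q) - s
            # the suffix part is certified by the binary search; verify
            # only the skipped prefix
            if p >= 0 and text[p : p + s] == pattern[:s]:
                found.append(p)
    found.sort()
    return MatchSet(occurrences=np.array(found, dtype=np.int64))
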