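"""Suffix-array construction over integer alphabets by induced sorting.

This is the SA-IS algorithm (Nong, Zhang & Chan): suffixes are classified
as L- or S-type, the leftmost-S (LMS) suffixes are sorted — recursively if
their substrings are not all distinct — and the full order is then induced
from them in two linear bucket scans. Bucket arrays are sized by the
alphabet upper bound, which for packed k-mer input is ``2**(b*k)``; that
bucket term is exactly why the memory of the direct sparse construction
grows again once ``sigma**k`` becomes large.

The hot loops are JIT-compiled with numba so multi-megabyte inputs sort in
seconds; the recursion driver stays in Python. ``naive_suffix_array`` is
the brute-force oracle used throughout the test-suite.

An optional :class:`AllocationLedger` counts, in words, the arrays a call
actually allocates (suffix array, type array and bucket arrays at every
recursion level), giving the peak working-set figure the direct-vs-sampled
construction comparison is based on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import SortingError

_L = 0
_S = 1

#: Largest alphabet for which dense per-character bucket arrays are
#: allocated. Beyond this the packed code space is far sparser than the
#: sequence is long, so block values are rank-compacted (order-preserving)
#: before sorting instead of allocating 2**(b*k) bucket words.
DENSE_BUCKET_LIMIT = 1 << 24


@dataclass(frozen=True)
class SuffixArray:
    """Positions of a sequence's suffixes in lexicographic order."""

    order: np.ndarray
    m: int


class AllocationLedger:
    """Tracks live allocation in words and remembers the peak.

    One "word" is one array element, regardless of dtype width — the
    resolution at which the construction-path comparison is stated.
    """

    def __init__(self) -> None:
        self.current = 0
        self.peak = 0

    def add(self, words: int) -> None:
        self.current += words
        if self.current > self.peak:
            self.peak = self.current

    def remove(self, words: int) -> None:
        self.current -= words


@njit(cache=True)
def _classify(seq):
    """Suffix types: 1 = S (smaller than successor), 0 = L."""
    n = seq.size
    t = np.empty(n, np.uint8)
    t[n - 1] = _S
    for i in range(n - 2, -1, -1):
        if seq[i] < seq[i + 1]:
            t[i] = _S
        elif seq[i] > seq[i + 1]:
            t[i] = _L
        else:
            t[i] = t[i + 1]
    return t


@njit(cache=True)
def _bucket_counts(seq, upper_bound):
    counts = np.zeros(upper_bound, np.int64)
    for i in range(seq.size):
        counts[seq[i]] += 1
    return counts


@njit(cache=True)
def _place_lms(seq, t, sa, tails):
    """Drop LMS suffixes at the ends of their buckets (text order)."""
    for i in range(seq.size - 1, 0, -1):
        if t[i] == _S and t[i - 1] == _L:
            c = seq[i]
            tails[c] -= 1
            sa[tails[c]] = i


@njit(cache=True)
def _induce_l(seq, t, sa, heads):
    for i in range(sa.size):
        j = sa[i] - 1
        if sa[i] > 0 and t[j] == _L:
            c = seq[j]
            sa[heads[c]] = j
            heads[c] += 1


@njit(cache=True)
def _induce_s(seq, t, sa, tails):
    for i in range(sa.size - 1, -1, -1):
        j = sa[i] - 1
        if sa[i] > 0 and t[j] == _S:
            c = seq[j]
            tails[c] -= 1
            sa[tails[c]] = j


@njit(cache=True)
def _collect_sorted_lms(t, sa, out):
    """LMS positions in the order they appear in the induced *sa*."""
    m = 0
    for i in range(sa.size):
        p = sa[i]
        if p > 0 and t[p] == _S and t[p - 1] == _L:
            out[m] = p
            m += 1
    return m


@njit(cache=True)
def _name_lms(seq, t, sorted_lms, m, name_of):
    """Assign names to LMS substrings in sorted order; equal substrings share a name.

    ``name_of`` is indexed by position//2 (no two LMS positions are adjacent).
    Returns the number of distinct names.
    """
    n = seq.size
    name = 0
    name_of[sorted_lms[0] // 2] = 0
    for idx in range(1, m):
        prev = sorted_lms[idx - 1]
        cur = sorted_lms[idx]
        equal = True
        i = 0
        while True:
            a = cur + i
            b = prev + i
            a_end = a == n - 1 or (i > 0 and t[a] == _S and t[a - 1] == _L)
            b_end = b == n - 1 or (i > 0 and t[b] == _S and t[b - 1] == _L)
            if a >= n or b >= n or seq[a] != seq[b] or t[a] != t[b]:
                equal = False
                break
            if a_end or b_end:
                equal = a_end and b_end
                break
            i += 1
        if not equal:
            name += 1
        name_of[cur // 2] = name
    return name + 1


@njit(cache=True)
def _place_sorted_lms(seq, sa, sorted_lms, m, tails):
    sa[:] = -1
    for i in range(m - 1, -1, -1):
        c = seq[sorted_lms[i]]
        tails[c] -= 1
        sa[tails[c]] = sorted_lms[i]


def _sais_rec(seq: np.ndarray, upper_bound: int, ledger: AllocationLedger | None) -> np.ndarray:
    n = seq.size
    sa = np.full(n, -1, dtype=np.int64)
    if ledger is not None:
        # suffix array + type array + two bucket boundary arrays
        level_words = 2 * n + 2 * upper_bound
        ledger.add(level_words)
    if n == 1:
        sa[0] = 0
        if ledger is not None:
            ledger.remove(level_words)
        return sa

    t = _classify(seq)
    counts = _bucket_counts(seq, upper_bound)
    tails = np.cumsum(counts)
    heads = tails - counts

    # Pass 1: approximate — LMS suffixes in text order, then induce.
    _place_lms(seq, t, sa, tails.copy())
    _induce_l(seq, t, sa, heads.copy())
    _induce_s(seq, t, sa, tails.copy())

    sorted_lms = np.empty(n // 2 + 1, dtype=np.int64)
    m = _collect_sorted_lms(t, sa, sorted_lms)

    if m > 0:
        name_of = np.full(n // 2 + 1, -1, dtype=np.int64)
        num_names = _name_lms(seq, t, sorted_lms, m, name_of)
        lms_in_order = sorted_lms[:m].copy()
        _text_order_lms(t, lms_in_order)
        if num_names < m:
            reduced = np.empty(m, dtype=np.int64)
            for i in range(m):
                reduced[i] = name_of[lms_in_order[i] // 2]
            if ledger is not None:
                ledger.add(m)  # reduced problem input
            sub_sa = _sais_rec(reduced, num_names, ledger)
            if ledger is not None:
                ledger.remove(m)
            sorted_lms = lms_in_order[sub_sa]
        else:
            # names already distinct: invert the naming directly
            sorted_lms = np.empty(m, dtype=np.int64)
            for i in range(m):
                sorted_lms[name_of[lms_in_order[i] // 2]] = lms_in_order[i]
        # Pass 2: exact — LMS suffixes in true sorted order, induce the rest.
        _place_sorted_lms(seq, sa, sorted_lms, m, tails.copy())
        _induce_l(seq, t, sa, heads.copy())
        _induce_s(seq, t, sa, tails.copy())

    if ledger is not None:
        ledger.remove(level_words)
    return sa


@njit(cache=True)
def _text_order_lms(t, lms):
    """Sort LMS positions back into text order (counting-free: they are few)."""
    lms.sort()


def sais(
    seq,
    alphabet_upper_bound: int,
    ledger: AllocationLedger | None = None,
) -> SuffixArray:
    """Suffix array of an integer sequence by induced sorting.

    Parameters
    ----------
    seq
        Non-empty sequence of unsigned integers whose last element is the
        unique minimum (the terminator).
    alphabet_upper_bound
        Exclusive upper bound on the values in *seq*; bucket arrays of this
        size are allocated, mirroring the sigma**k bucket term of the
        packed construction. Bounds above :data:`DENSE_BUCKET_LIMIT` are
        first reduced by an order-preserving rank compaction of the values,
        so very sparse packed alphabets stay feasible.
    ledger
        Optional :class:`AllocationLedger` that accumulates the words
        allocated at every recursion level.

    Raises
    ------
    SortingError
        On an empty sequence, a missing unique terminator, or an element
        outside ``[0, alphabet_upper_bound)``.
    """
    arr = np.ascontiguousarray(seq, dtype=np.int64)
    if arr.size == 0:
        raise SortingError("empty sequence")
    if arr.min() < 0 or arr.max() >= alphabet_upper_bound:
        raise SortingError(
            f"element out of range [0, {alphabet_upper_bound})"
        )
    terminator = arr[-1]
    if arr.size > 1 and (arr[:-1] <= terminator).any():
        raise SortingError("missing unique terminator")
    bound = int(alphabet_upper_bound)
    if bound > DENSE_BUCKET_LIMIT:
        # order-preserving rank compaction: np.unique is sorted, so the
        # relabelled sequence has the same suffix order (and the
        # terminator stays the unique minimum, rank 0)
        uniq, arr = np.unique(arr, return_inverse=True)
        arr = np.ascontiguousarray(arr, dtype=np.int64)
        bound = uniq.size
    order = _sais_rec(arr, bound, ledger)
    return SuffixArray(order=order, m=arr.size)


def naive_suffix_array(seq) -> SuffixArray:
    """Brute-force suffix array by direct comparison of all suffixes.

    The independent oracle for :func:`sais`: quadratic, no terminator
    requirement, identical contract where sais's preconditions hold.
    """
    lst = [int(x) for x in seq]
    if not lst:
        raise SortingError("empty sequence")
    order = sorted(range(len(lst)), key=lambda i: lst[i:])
    return SuffixArray(order=np.array(order, dtype=np.int64), m=len(lst))
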