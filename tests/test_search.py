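import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsesa import SearchError, build_direct, find_all, suffix_range
from tests.conftest import naive_scan


@pytest.fixture(scope="module")
def banana_ssa():
    return build_direct("banana", 2)


class TestSuffixRange:
    def test_prefix_range_covers_matching_sampled_suffixes(self, banana_ssa):
        # sampled order is ["banana", "na", "nana"] at positions [0, 4, 2]
        assert suffix_range(banana_ssa, "banana", "na") == (1, 3)
        assert suffix_range(banana_ssa, "banana", "banana") == (0, 1)
        assert suffix_range(banana_ssa, "banana", "z") == (2 + 1, 3)  # empty

    def test_empty_range_is_well_formed(self, banana_ssa):
        lo, hi = suffix_range(banana_ssa, "banana", "qq")
        assert lo == hi

    def test_empty_query_rejected(self, banana_ssa):
        with pytest.raises(SearchError, match="empty"):
            suffix_range(banana_ssa, "banana", "")


class TestFindAll:
    def test_finds_all_occurrences(self, banana_ssa):
        assert list(find_all(banana_ssa, "banana", "ana")) == [1, 3]
        assert list(find_all(banana_ssa, "banana", "qq")) == []
        assert list(find_all(banana_ssa, "banana", "na")) == [2, 4]

    def test_k1_search_never_needs_verification(self):
        text = "mississippi"
        ssa = build_direct(text, 1)
        assert list(find_all(ssa, text, "ssi")) == naive_scan(text, "ssi")
        assert list(find_all(ssa, text, "i")) == naive_scan(text, "i")

    def test_short_pattern_rejected_without_fallback(self, banana_ssa):
        with pytest.raises(SearchError, match="shorter than sparseness"):
            find_all(banana_ssa, "banana", "a")

    def test_short_pattern_scan_fallback(self, banana_ssa):
        matches = find_all(banana_ssa, "banana", "a", scan_short=True)
        assert list(matches) == [1, 3, 5]

    def test_match_set_membership(self, banana_ssa):
        matches = find_all(banana_ssa, "banana", "ana")
        assert 1 in matches and 3 in matches and 2 not in matches
        assert len(matches) == 2

    @settings(deadline=None, max_examples=100)
    @given(
        st.text(alphabet="AB", min_size=4, max_size=150),
        st.integers(min_value=1, max_value=5),
        st.data(),
    )
    def test_matches_naive_scan(self, text, k, data):
        ssa = build_direct(text, k)
        # bias towards planted substrings so hits are common
        if data.draw(st.booleans()):
            i = data.draw(st.integers(0, len(text) - 1))
            m = data.draw(st.integers(k, k + 6))
            pattern = text[i : i + m]
            if len(pattern) < k:
                return
        else:
            pattern = data.draw(st.text(alphabet="AB", min_size=k, max_size=k + 6))
        assert list(find_all(ssa, text, pattern)) == naive_scan(text, pattern)

    def test_occurrences_at_text_edges_and_block_boundaries(self):
        text = "ABCABCABCABC"
        for k in (2, 3, 4):
            ssa = build_direct(text, k)
            for pattern in ("ABCA", "CABC", "ABCABCABCABC", "BCAB"):
                if len(pattern) < k:
                    continue
                assert list(find_all(ssa, text, pattern)) == naive_scan(text, pattern)

    def test_each_occurrence_found_by_exactly_one_shift(self, rng, random_text):
        # count raw candidate discoveries across shifts: no deduplication needed
        for seed in range(20):
            text = random_text(3, 120, seed)
            k = int(rng.integers(2, 6))
            ssa = build_direct(text, k)
            i = int(rng.integers(0, len(text) - k))
            pattern = text[i : i + k + 2]
            if len(pattern) < k:
                continue
            discoveries = []
            for s in range(k):
                lo, hi = suffix_range(ssa, text, pattern[s:])
                for q in ssa.positions[lo:hi]:
                    p = int(q) - s
                    if p >= 0 and text[p : p + s] == pattern[:s]:
                        discoveries.append(p)
            assert sorted(discoveries) == naive_scan(text, pattern)
            assert len(discoveries) == len(set(discoveries))
            for p in discoveries:
                assert (p + ((k - p % k) % k)) % k == 0  # the unique shift

    def test_binary_search_count_is_min_k_m(self, monkeypatch, banana_ssa):
        import sparsesa.search as search_mod

        calls = []
        original = search_mod.suffix_range

        def counting(ssa, text, query):
            calls.append(query)
            return original(ssa, text, query)

        monkeypatch.setattr(search_mod, "suffix_range", counting)
        search_mod.find_all(banana_ssa, "banana", "anan")
        assert len(calls) == min(banana_ssa.k, 4)
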