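import numpy as np
import pytest
from hypothesis import settings

from sparsesa import generate_synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def random_text():
    """Factory for uniform random texts over the first *sigma* uppercase letters."""

    def make(sigma: int, length: int, seed: int) -> str:
        return generate_synthetic(
            "".join(chr(ord("A") + i) for i in range(sigma)), length, seed
        )

    return make


def naive_scan(text: str, pattern: str) -> list[int]:
    """Independent occurrence oracle: repeated str.find."""
    hits = []
    i = text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def brute_force_ssa(text: str, k: int) -> list[int]:
    """Independent SSA oracle: sort sampled suffixes by direct string comparison."""
    sampled = range(0, len(text), k)
    return sorted(sampled, key=lambda p: text[p:])
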