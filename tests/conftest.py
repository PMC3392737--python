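"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's optimized code paths:
hits are detected by direct pattern scanning, overlap complexity by
character-by-character counting, and sensitivities by exhaustive
enumeration of all binary regions — so they can certify the fast
implementations on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from spacedseeds import Seed, SeedSet, contiguous_seed


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_random_seed(rng: np.random.Generator, w: int, length: int) -> Seed:
    """Random seed of given weight/length with 1s pinned at both ends."""
    if length == w:
        return contiguous_seed(w)
    assert w >= 2
    interior = rng.choice(length - 2, size=w - 2, replace=False) + 1
    pat = ["*"] * length
    pat[0] = pat[-1] = "1"
    for t in interior:
        pat[t] = "1"
    return Seed("".join(pat))


def make_random_set(rng: np.random.Generator, k: int, w: int, lmin: int, lmax: int) -> SeedSet:
    lengths = rng.integers(max(lmin, w), lmax + 1, size=k)
    return SeedSet([make_random_seed(rng, w, int(l)) for l in lengths])


def seed_hits(pattern: str, region: str) -> bool:
    """Direct scan: does the seed hit the 0/1 region at any offset?"""
    l = len(pattern)
    for i in range(len(region) - l + 1):
        if all(region[i + j] == "1" for j in range(l) if pattern[j] == "1"):
            return True
    return False


def set_hits(S: SeedSet, region: str) -> bool:
    return any(seed_hits(s.pattern, region) for s in S)


def exhaustive_sensitivity(S: SeedSet, N: int, p: float) -> float:
    """Sum of Bernoulli string probabilities over all 2^N hit regions."""
    total = 0.0
    for bits in itertools.product("01", repeat=N):
        region = "".join(bits)
        if set_hits(S, region):
            ones = region.count("1")
            total += p**ones * (1.0 - p) ** (N - ones)
    return total


def naive_oc_pair(pa: str, pb: str) -> int:
    """Character-level OC: slide one pattern across the other."""
    la, lb = len(pa), len(pb)
    total = 0
    for shift in range(-(lb - 1), la):
        sigma = sum(
            1
            for t in range(lb)
            if 0 <= t + shift < la and pa[t + shift] == "1" and pb[t] == "1"
        )
        total += 2**sigma
    return total


def naive_oc_set(patterns: list[str]) -> int:
    total = 0
    for i in range(len(patterns)):
        for j in range(i, len(patterns)):
            total += naive_oc_pair(patterns[i], patterns[j])
    return total


def all_legal_patterns(max_len: int):
    """Every legal seed pattern (starts/ends with 1) up to max_len."""
    yield "1"
    for l in range(2, max_len + 1):
        for mid in itertools.product("1*", repeat=l - 2):
            yield "1" + "".join(mid) + "1"
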