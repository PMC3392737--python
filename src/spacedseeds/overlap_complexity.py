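"""Overlap complexity of seed pairs and seed sets.

Two seeds of lengths ``la`` and ``lb`` can overlap in ``la + lb - 1``
relative placements.  For shift ``r`` let ``sigma[r]`` be the number of
positions where both seeds carry a ``1``.  The overlap complexity of the
pair is

    OC(a, b) = sum_r 2**sigma[r]

and for a multiple seed ``S = {s_1, ..., s_k}``

    OC(S) = sum_{i <= j} OC(s_i, s_j)

including the self-terms ``i == j``.  Low overlap complexity is strongly
correlated with high sensitivity, which is what makes it a useful
polynomial-time surrogate objective when designing seed sets.

Two evaluation routes are provided: :func:`oc_pair` counts coincident 1s
by direct character comparison, while :func:`oc_pair_fast` works on the
integer bitmask images, AND-ing shifted masks and counting bits through a
precomputed block popcount table (8- or 16-bit blocks).  Both return
exact integers and agree on every input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seed_model import Seed, SeedSet

__all__ = [
    "SigmaArray",
    "PopcountTable",
    "sigma_array",
    "oc_pair",
    "oc_set",
    "build_popcount_table",
    "oc_pair_fast",
    "oc_set_fast",
]

# sigma values are plain lists of ints; the alias documents intent.
SigmaArray = list


def sigma_array(a: Seed, b: Seed) -> SigmaArray:
    """Coincident-1 counts for every relative shift of the pair ``(a, b)``.

    Entry ``r`` (0 <= r <= la + lb - 2) corresponds to the placement in
    which character ``b[t]`` faces character ``a[t + r - lb + 1]``; shift
    ``r`` is the distance between the right end of ``b`` and the left end
    of ``a``, so ``r = 0`` is the single-character overlap at ``a``'s left
    edge and the index grows as ``b`` slides rightwards.
    """
    pa, pb = a.pattern, b.pattern
    la, lb = a.length, b.length
    out = []
    for r in range(la + lb - 1):
        d = r - lb + 1
        count = 0
        for t in range(lb):
            u = t + d
            if 0 <= u < la and pa[u] == "1" and pb[t] == "1":
                count += 1
        out.append(count)
    return out


def oc_pair(a: Seed, b: Seed) -> int:
    """Overlap complexity of a seed pair by direct position comparison."""
    return sum(1 << s for s in sigma_array(a, b))


def oc_set(S: SeedSet) -> int:
    """Overlap complexity of a multiple seed: all pairs i <= j, self-terms included."""
    total = 0
    for i in range(S.k):
        for j in range(i, S.k):
            total += oc_pair(S[i], S[j])
    return total


@dataclass(frozen=True)
class PopcountTable:
    """Lookup table mapping every ``block_bits``-bit integer to its bit count."""

    block_bits: int
    table: np.ndarray

    def __post_init__(self) -> None:
        if self.block_bits not in (8, 16):
            raise ValueError(f"block_bits must be 8 or 16, got {self.block_bits}")

    def popcount(self, x: int) -> int:
        """Number of set bits of a non-negative integer, block by block."""
        bits, table, mask = self.block_bits, self.table, (1 << self.block_bits) - 1
        count = 0
        while x:
            count += int(table[x & mask])
            x >>= bits
        return count


def build_popcount_table(block_bits: int = 16) -> PopcountTable:
    """Precompute bit counts for all ``2**block_bits`` block values."""
    if block_bits not in (8, 16):
        raise ValueError(f"block_bits must be 8 or 16, got {block_bits}")
    n = 1 << block_bits
    table = np.zeros(n, dtype=np.uint8)
    for i in range(1, n):
        table[i] = table[i >> 1] + (i & 1)
    return PopcountTable(block_bits, table)


_DEFAULT_TABLE: PopcountTable | None = None


def _default_table() -> PopcountTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_popcount_table(16)
    return _DEFAULT_TABLE


def oc_pair_fast(a: Seed, b: Seed, table: PopcountTable | None = None) -> int:
    """Bit-parallel overlap complexity: shift, AND, table popcount per shift.

    Returns exactly :func:`oc_pair`(a, b) for every pair.
    """
    if table is None:
        table = _default_table()
    ma = a.mask << (b.length - 1)  # pre-align so each shift is one right-shift
    mb = b.mask
    total = 0
    for r in range(a.length + b.length - 1):
        total += 1 << table.popcount((ma >> r) & mb)
    return total


def oc_set_fast(S: SeedSet, table: PopcountTable | None = None) -> int:
    if table is None:
        table = _default_table()
    total = 0
    for i in range(S.k):
        for j in range(i, S.k):
            total += oc_pair_fast(S[i], S[j], table)
    return total
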