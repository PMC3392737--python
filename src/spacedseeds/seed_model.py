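"""Spaced-seed representation and plain-text seed-file I/O.

A spaced seed is a string over the alphabet ``{1, *}``: a ``1`` marks a
position where the alignment must contain a match, a ``*`` is a don't-care
position.  The *weight* ``w`` is the number of 1s and the *length* ``l``
is the total number of characters.  Because a don't-care at either end of
a seed never helps, seeds are required to start and end with a ``1``.

Each seed also carries an integer bitmask image (``1`` -> bit 1,
``*`` -> bit 0, leftmost character most significant), e.g. ``1**11`` maps
to ``0b10011 == 19``.  Masks are ordinary Python integers, so seeds of any
length are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Seed",
    "SeedSet",
    "parse_seed",
    "contiguous_seed",
    "unmask",
    "read_seed_file",
    "write_seed_file",
]

_ALPHABET = frozenset("1*")


@dataclass(frozen=True)
class Seed:
    """A single spaced seed with its derived weight, length and bitmask."""

    pattern: str
    weight: int = field(init=False)
    length: int = field(init=False)
    mask: int = field(init=False)

    def __post_init__(self) -> None:
        p = self.pattern
        if not p:
            raise ValueError("empty seed pattern")
        bad = set(p) - _ALPHABET
        if bad:
            raise ValueError(f"illegal seed characters {sorted(bad)!r}; expected only '1' and '*'")
        if p[0] != "1" or p[-1] != "1":
            raise ValueError(f"seed {p!r} must start and end with '1'")
        object.__setattr__(self, "weight", p.count("1"))
        object.__setattr__(self, "length", len(p))
        object.__setattr__(self, "mask", int(p.replace("*", "0"), 2))

    def __str__(self) -> str:
        return self.pattern

    @property
    def ones(self) -> tuple[int, ...]:
        """Indices of the match positions, left to right."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "1")

    @property
    def stars(self) -> tuple[int, ...]:
        """Indices of the don't-care positions."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "*")


def parse_seed(text: str) -> Seed:
    """Parse a seed string over ``{1, *}`` into a validated :class:`Seed`."""
    return Seed(text.strip())


def contiguous_seed(w: int) -> Seed:
    """The BLAST-style contiguous seed of ``w`` consecutive 1s."""
    if w < 1:
        raise ValueError(f"weight must be >= 1, got {w}")
    return Seed("1" * w)


def unmask(mask: int, length: int) -> str:
    """Inverse of the pattern -> bitmask conversion."""
    if mask < 0 or length < 1 or mask >= (1 << length):
        raise ValueError(f"mask {mask} does not fit in length {length}")
    return format(mask, f"0{length}b").replace("0", "*")


class SeedSet:
    """An ordered multiple spaced seed ``S = {s_1, ..., s_k}``.

    Order is significant: pair indices ``(i, j)`` in overlap-complexity
    sums refer to it.  In design mode all seeds share one weight so that
    specificity (the random-hit rate, governed by the weight) is uniform
    across the set; evaluation of mixed-weight sets is permitted by
    passing ``require_uniform_weight=False``.
    """

    def __init__(self, seeds: Iterable[Seed | str], require_uniform_weight: bool = False):
        self.seeds: list[Seed] = [s if isinstance(s, Seed) else parse_seed(s) for s in seeds]
        if not self.seeds:
            raise ValueError("a seed set needs at least one seed")
        if require_uniform_weight:
            weights = {s.weight for s in self.seeds}
            if len(weights) > 1:
                raise ValueError(f"seeds must share a common weight, got weights {sorted(weights)}")

    @property
    def k(self) -> int:
        return len(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self) -> Iterator[Seed]:
        return iter(self.seeds)

    def __getitem__(self, i: int) -> Seed:
        return self.seeds[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeedSet):
            return NotImplemented
        return [s.pattern for s in self.seeds] == [s.pattern for s in other.seeds]

    def __repr__(self) -> str:
        return f"SeedSet({[s.pattern for s in self.seeds]})"

    def copy(self) -> "SeedSet":
        return SeedSet(self.seeds)

    @property
    def patterns(self) -> list[str]:
        return [s.pattern for s in self.seeds]


def read_seed_file(path: str | Path, require_uniform_weight: bool = False) -> SeedSet:
    """Read a plain-text seed file: one seed per line, ``#`` comments ignored."""
    seeds = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seeds.append(parse_seed(line))
    if not seeds:
        raise ValueError(f"no seeds found in {path}")
    return SeedSet(seeds, require_uniform_weight=require_uniform_weight)


def write_seed_file(path: str | Path, seeds: SeedSet, header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    lines.extend(s.pattern for s in seeds)
    Path(path).write_text("\n".join(lines) + "\n")
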