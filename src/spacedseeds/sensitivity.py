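"""Exact seed sensitivity under the Bernoulli alignment model.

An alignment is modelled as a random binary region ``R`` of length ``N``
whose positions are independently a match (1) with probability ``p`` (the
*similarity*).  A seed ``s`` hits ``R`` at offset ``i`` when every
1-position ``j`` of the seed faces a match: ``s[j] = 1  =>  R[i+j] = 1``.
A multiple seed hits when any member does.  The *sensitivity* of a seed
set is the probability that it hits ``R``.

The computation is exact: the hit predicate is compiled into a complete
deterministic automaton over ``{0, 1}`` with a single absorbing hit
state, and the hit probability is obtained by pushing the state
distribution forward ``N`` steps.

Automaton states track, for each seed, the set of seed-prefix lengths
compatible with the suffix of the region read so far (a subset
construction over seed-compatible prefixes, deduplicated, in the spirit
of Aho-Corasick).  Reading symbol ``c`` extends an active prefix of
length ``j`` to ``j + 1`` whenever ``s[j] = *`` or ``c = 1``; completing
a full seed is a hit.  State counts stay modest for the seed shapes used
in practice, but heavy multiple seeds can blow up exponentially, so
construction is guarded by an explicit state budget and fails loudly
rather than thrash.

Probabilities are propagated in plain linear space: with region lengths
of at most a few hundred and ``p`` bounded away from 0 and 1, the mass
in play never approaches the underflow threshold.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

from .seed_model import Seed, SeedSet

__all__ = [
    "BernoulliModel",
    "HitAutomaton",
    "StateBudgetExceeded",
    "build_hit_automaton",
    "sensitivity",
    "contiguous_sensitivity",
    "format_percent",
]

DEFAULT_STATE_BUDGET = 2_000_000


@dataclass(frozen=True)
class BernoulliModel:
    """Region length ``N`` and per-position match probability ``p``."""

    N: int
    p: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"region length N must be >= 1, got {self.N}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"similarity p must lie in (0, 1), got {self.p}")


class StateBudgetExceeded(RuntimeError):
    """Hit-automaton construction exceeded its state budget."""

    def __init__(self, budget: int):
        super().__init__(
            f"hit automaton exceeded the state budget of {budget} states; "
            f"raise state_budget to evaluate this seed set exactly"
        )
        self.budget = budget


@dataclass
class HitAutomaton:
    """Complete DFA over {0, 1}; reaching ``hit`` means some seed has hit."""

    n_states: int
    start: int
    hit: int
    on_zero: np.ndarray  # successor state under symbol 0, shape (n_states,)
    on_one: np.ndarray  # successor state under symbol 1

    def accepts(self, bits) -> bool:
        """Drive the automaton over a 0/1 sequence (ints or characters)."""
        state = self.start
        for b in bits:
            state = int(self.on_one[state]) if b in (1, "1") else int(self.on_zero[state])
            if state == self.hit:
                return True
        return state == self.hit


def build_hit_automaton(
    S: SeedSet | Seed, state_budget: int = DEFAULT_STATE_BUDGET
) -> HitAutomaton:
    """Compile a seed set's hit predicate into a deterministic automaton.

    Each non-hit state is the tuple, over seeds, of bitmasks of active
    prefix lengths (bit ``j`` set means the last ``j`` region symbols are
    compatible with the seed's first ``j`` positions).  Transitions are
    one shift-and-mask per seed, and states are deduplicated as they are
    discovered by breadth-first search.
    """
    if isinstance(S, Seed):
        S = SeedSet([S])
    lengths = [s.length for s in S]
    full = [(1 << l) - 1 for l in lengths]
    # bit j of ext0: prefix j may extend on a mismatch, i.e. s[j] == '*'
    ext0 = [sum(1 << j for j in s.stars) for s in S]
    hit_bit = [1 << l for l in lengths]

    HIT = 0
    start_key = tuple(1 for _ in lengths)  # only the empty prefix is active
    ids: dict[tuple[int, ...], int] = {start_key: 1}
    on_zero: list[int] = [HIT]
    on_one: list[int] = [HIT]
    queue = deque([start_key])
    while queue:
        key = queue.popleft()
        for symbol in (0, 1):
            nxt: tuple[int, ...] | None = []
            for m, e0, f, hb in zip(key, ext0, full, hit_bit):
                m2 = (((m & e0) << 1) | 1) if symbol == 0 else ((m << 1) | 1)
                if m2 & hb:
                    nxt = None  # a seed completed: hit
                    break
                nxt.append(m2 & f)
            if nxt is None:
                succ = HIT
            else:
                nkey = tuple(nxt)
                succ = ids.get(nkey)
                if succ is None:
                    succ = len(ids) + 1
                    if succ + 1 > state_budget:
                        raise StateBudgetExceeded(state_budget)
                    ids[nkey] = succ
                    queue.append(nkey)
            if symbol == 0:
                on_zero.append(succ)
            else:
                on_one.append(succ)
    n = len(ids) + 1
    # ids are assigned in BFS discovery order, which matches append order
    return HitAutomaton(
        n_states=n,
        start=1,
        hit=HIT,
        on_zero=np.asarray(on_zero, dtype=np.int64),
        on_one=np.asarray(on_one, dtype=np.int64),
    )


def sensitivity(
    S: SeedSet | Seed,
    model: BernoulliModel,
    state_budget: int = DEFAULT_STATE_BUDGET,
    automaton: HitAutomaton | None = None,
) -> float:
    """Exact probability that the seed set hits a Bernoulli(N, p) region."""
    if automaton is None:
        automaton = build_hit_automaton(S, state_budget=state_budget)
    n, p = automaton.n_states, model.p
    v = np.zeros(n)
    v[automaton.start] = 1.0
    on0, on1 = automaton.on_zero, automaton.on_one
    for _ in range(model.N):
        v = np.bincount(on0, weights=v * (1.0 - p), minlength=n) + np.bincount(
            on1, weights=v * p, minlength=n
        )
    return float(v[automaton.hit])


def contiguous_sensitivity(w: int, model: BernoulliModel) -> float:
    """Probability of a run of ``w`` consecutive matches in ``N`` trials.

    Independent O(N) route for contiguous seeds: the no-run probability
    ``q_n`` obeys the first-occurrence recurrence

        q_n = q_{n-1} - (1 - p) * p**w * q_{n-w-1}    for n > w,

    with ``q_n = 1`` for ``n < w`` and ``q_w = 1 - p**w``.  Serves as a
    cross-check oracle for the general automaton route, with which it
    agrees to full double precision.
    """
    if w < 1:
        raise ValueError(f"weight must be >= 1, got {w}")
    N, p = model.N, model.p
    if N < w:
        return 0.0
    pw = p**w
    c = (1.0 - p) * pw
    # q[n] = P(no run of w ones in n trials); index shifted so q[-1] = 1
    q = [1.0] * (w + 1)  # q_{-1} .. q_{w-1}
    q.append(1.0 - pw)  # q_w
    for n in range(w + 1, N + 1):
        q.append(q[-1] - c * q[n - w - 1 + 1])
    return 1.0 - q[-1]


def format_percent(prob: float, decimals: int = 4) -> str:
    """Render a probability as a percentage, round-half-even, fixed decimals."""
    quantum = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(prob * 100.0)).quantize(quantum, rounding=ROUND_HALF_EVEN))
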