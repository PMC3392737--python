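"""Incremental hill climbing on overlap complexity.

The optimizer repeatedly applies the single ``(1, *)`` swap — exchanging
a match position with a don't-care position inside one seed — that most
reduces the overlap complexity of the set, until no swap strictly lowers
it.  Endpoints are never offered for swapping, so the start/end-with-1
convention survives every move, and seed weight and length are invariant
throughout.

Evaluating a candidate swap from scratch would cost a full OC
recomputation; instead the following structures are maintained so a swap
can be scored by local corrections only:

``OM`` matrices
    for each pair ``i <= j`` an ``l_i x l_j`` matrix with entry 1 where
    both seeds have a 1, 0 where both have a ``*``, and -1 otherwise.
``sigma`` arrays
    per pair, the coincident-1 count for each of the ``l_i + l_j - 1``
    relative shifts; entry ``r`` sums the NW-SE diagonal of ``OM`` with
    row - col = r - l_j + 1.
``OCM`` matrix
    per pair, ``OCM[i][j] = sum_r 2**sigma_ij[r] = OC(s_i, s_j)``.

Swapping positions ``(i, j)`` of seed ``q`` only touches, in each pair
involving ``q``, the sigma entries on the diagonals through columns (or
rows) ``i`` and ``j`` — a removed 1 decrements sigma wherever the partner
seed has a 1 facing it, an added 1 increments it — so the new pair OC is
available in time linear in the seed length (:func:`update_sigma`).

The best-swap scan itself evaluates all candidate swaps of a seed against
all pairs in one vectorized pass: with ``P[r] = 2**sigma[r]`` the OC
delta of moving the 1 from column ``i`` to column ``j`` is

    -1/2 * sum_{t in D_i} P[t]  +  sum_{t in A_j} P[t]
    -1/2 * sum_{t in D_i & A_j} P[t]

where ``D_i``/``A_j`` are the diagonals hit by the removal/addition.  All
quantities involved are integers below 2**53, so the float arithmetic is
exact; the winning candidate is nevertheless re-scored through the exact
integer path before being returned.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .overlap_complexity import SigmaArray, sigma_array
from .seed_model import Seed, SeedSet, contiguous_seed
from .sensitivity import (
    DEFAULT_STATE_BUDGET,
    BernoulliModel,
    StateBudgetExceeded,
    sensitivity,
)

__all__ = [
    "OverlapState",
    "SwapCandidate",
    "DesignConfig",
    "DesignReport",
    "init_state",
    "oc_from_sigma",
    "update_sigma",
    "best_swap",
    "apply_swap",
    "climb",
    "random_seed_set",
    "resolve_lengths",
    "design",
]

logger = logging.getLogger(__name__)

PairKey = tuple[int, int]


@dataclass
class SwapCandidate:
    """A prospective ``(1, *)`` exchange inside seed ``seed_index``."""

    seed_index: int
    one_pos: int
    star_pos: int
    candidate_oc: int


@dataclass
class OverlapState:
    """Incrementally maintained OM / sigma / OCM bookkeeping for a seed set."""

    om: dict[PairKey, np.ndarray]
    sigma: dict[PairKey, SigmaArray]
    ocm: dict[PairKey, int]
    total_oc: int


def _om_matrix(a: Seed, b: Seed) -> np.ndarray:
    va = np.frombuffer(a.pattern.encode(), dtype=np.uint8) == ord("1")
    vb = np.frombuffer(b.pattern.encode(), dtype=np.uint8) == ord("1")
    both1 = va[:, None] & vb[None, :]
    both0 = ~va[:, None] & ~vb[None, :]
    return both1.astype(np.int8) - (~both1 & ~both0).astype(np.int8)


def init_state(S: SeedSet) -> OverlapState:
    """Build all matrices and arrays from their definitions."""
    om, sig, ocm = {}, {}, {}
    total = 0
    for i in range(S.k):
        for j in range(i, S.k):
            om[i, j] = _om_matrix(S[i], S[j])
            sig[i, j] = sigma_array(S[i], S[j])
            ocm[i, j] = oc_from_sigma(sig[i, j])
            total += ocm[i, j]
    return OverlapState(om=om, sigma=sig, ocm=ocm, total_oc=total)


def oc_from_sigma(sig: Sequence[int]) -> int:
    """OC of a pair from its sigma array: sum of left-shifts 1 << sigma[t]."""
    return sum(1 << s for s in sig)


def _canonical(r: int, q: int) -> PairKey:
    return (r, q) if r <= q else (q, r)


def update_sigma(
    state: OverlapState, pair: PairKey, swap: SwapCandidate, S: SeedSet
) -> SigmaArray:
    """Sigma array the pair would have after the swap; the state is not touched.

    ``pair`` may be given in either order; it is canonicalized to
    ``(min, max)``.  The self-pair ``(q, q)`` is special: the swap changes
    both the row and the column seed, so four diagonal families move.
    """
    a_idx, b_idx = _canonical(*pair)
    q, i, j = swap.seed_index, swap.one_pos, swap.star_pos
    if q not in (a_idx, b_idx):
        raise ValueError(f"swap is in seed {q}, not in pair {pair}")
    pa, pb = S[a_idx].pattern, S[b_idx].pattern
    pq = S[q].pattern
    if not (0 < i < len(pq) - 1) or pq[i] != "1":
        raise ValueError(f"one_pos {i} of seed {q} is not an interior '1'")
    if pq[j] != "*":
        raise ValueError(f"star_pos {j} of seed {q} does not hold a '*'")
    lb = len(pb)
    sig = list(state.sigma[a_idx, b_idx])
    off = lb - 1

    if a_idx == b_idx:
        # both roles of the seed change; diagonals through rows and
        # columns i and j all move, with the four corner cells handled
        # exactly: (i,i) 1 -> 0, (j,j) 0 -> 1, (i,j) and (j,i) stay -1
        for t, ch in enumerate(pa):
            if ch != "1" or t == i:
                continue
            sig[t - i + off] -= 1  # column i loses its 1 against row t
            sig[t - j + off] += 1  # column j gains a 1 against row t
            sig[i - t + off] -= 1  # row i
            sig[j - t + off] += 1  # row j
        sig[off] -= 1  # cell (i, i)
        sig[off] += 1  # cell (j, j)
        return sig

    if q == b_idx:  # swap in the column seed
        for t, ch in enumerate(pa):
            if ch == "1":
                sig[t - i + off] -= 1
                sig[t - j + off] += 1
    else:  # swap in the row seed
        for t, ch in enumerate(pb):
            if ch == "1":
                sig[i - t + off] -= 1
                sig[j - t + off] += 1
    return sig


def _candidate_oc_exact(state: OverlapState, S: SeedSet, swap: SwapCandidate) -> int:
    total = state.total_oc
    for r in range(S.k):
        key = _canonical(r, swap.seed_index)
        total += oc_from_sigma(update_sigma(state, key, swap, S)) - state.ocm[key]
    return total


def best_swap(state: OverlapState, S: SeedSet) -> SwapCandidate | None:
    """The swap minimizing OC over all seeds and legal (1, *) position pairs.

    Returns ``None`` when the set is a local optimum (no swap strictly
    lowers OC).  Ties are broken by scan order: ascending seed index,
    then one position, then star position.  The state is left unchanged.
    """
    best: SwapCandidate | None = None
    for q in range(S.k):
        sq = S[q]
        ones = np.array([t for t in sq.ones if 0 < t < sq.length - 1], dtype=np.int64)
        stars = np.asarray(sq.stars, dtype=np.int64)
        if ones.size == 0 or stars.size == 0:
            continue
        delta = np.zeros((ones.size, stars.size))
        for r in range(S.k):
            if r == q:
                delta += _self_pair_deltas(state, q, sq, ones, stars)
            else:
                delta += _cross_pair_deltas(state, S, r, q, ones, stars)
        flat = int(np.argmin(delta))
        d = float(delta.flat[flat])
        cand_total = state.total_oc + int(d)
        if d < 0 and (best is None or cand_total < best.candidate_oc):
            ii, jj = divmod(flat, stars.size)
            cand = SwapCandidate(q, int(ones[ii]), int(stars[jj]), cand_total)
            exact = _candidate_oc_exact(state, S, cand)
            assert exact == cand_total, "float fast path diverged from exact OC"
            best = cand
    return best


def _cross_pair_deltas(
    state: OverlapState,
    S: SeedSet,
    r: int,
    q: int,
    ones_q: np.ndarray,
    stars_q: np.ndarray,
) -> np.ndarray:
    """OC deltas of every (1, *) swap in seed q against the pair (r, q)."""
    a_idx, b_idx = _canonical(r, q)
    sig = np.asarray(state.sigma[a_idx, b_idx], dtype=np.int64)
    P = np.exp2(sig)  # exact: sigma <= w <= a few tens
    other = S[r]
    ones_o = np.asarray(other.ones, dtype=np.int64)
    off = S[b_idx].length - 1
    if q == b_idx:  # q is the column seed: diagonals t - c + off
        idx_d = ones_o[None, :] - ones_q[:, None] + off
        idx_a = ones_o[None, :] - stars_q[:, None] + off
    else:  # q is the row seed: diagonals c - t + off
        idx_d = ones_q[:, None] - ones_o[None, :] + off
        idx_a = stars_q[:, None] - ones_o[None, :] + off
    SD = P[idx_d].sum(axis=1)  # mass removed (halved) per one_pos
    SA = P[idx_a].sum(axis=1)  # mass doubled... added per star_pos
    # overlap correction: diagonals hit by both the removal and the addition
    tt = np.repeat(ones_o, ones_o.size)
    uu = np.tile(ones_o, ones_o.size)
    dd = uu - tt
    if q == b_idx:
        val = P[tt[None, :] - ones_q[:, None] + off]  # (nI, w^2)
    else:
        val = P[ones_q[:, None] - tt[None, :] + off]
    cond = dd[None, None, :] == (stars_q[None, :, None] - ones_q[:, None, None])
    C = np.einsum("ik,ijk->ij", val, cond.astype(np.float64))
    return -0.5 * SD[:, None] + SA[None, :] - 0.5 * C


def _self_pair_deltas(
    state: OverlapState, q: int, sq: Seed, ones_q: np.ndarray, stars_q: np.ndarray
) -> np.ndarray:
    """OC deltas of every swap in seed q against its own self-pair.

    The swap changes both roles of the seed, so the post-swap sigma is
    cheapest to obtain as the autocorrelation of the swapped 0/1 vector.
    """
    v = (np.frombuffer(sq.pattern.encode(), dtype=np.uint8) == ord("1")).astype(np.float64)
    oc_self = float(state.ocm[q, q])
    delta = np.empty((ones_q.size, stars_q.size))
    for a, i in enumerate(ones_q):
        vi = v.copy()
        vi[i] = 0.0
        for b, j in enumerate(stars_q):
            vj = vi.copy()
            vj[j] = 1.0
            sig = np.correlate(vj, vj, mode="full")
            delta[a, b] = np.exp2(sig).sum() - oc_self
    return delta


def climb(S: SeedSet, state: OverlapState | None = None) -> tuple[SeedSet, list[int]]:
    """Greedy descent to a local optimum of OC.

    Returns the optimized set (the input is not modified) and the strictly
    decreasing OC trace, starting at the initial OC.
    """
    S = S.copy()
    if state is None:
        state = init_state(S)
    trace = [state.total_oc]
    while (cand := best_swap(state, S)) is not None:
        apply_swap(state, S, cand)
        trace.append(state.total_oc)
    return S, trace


def apply_swap(state: OverlapState, S: SeedSet, swap: SwapCandidate) -> tuple[OverlapState, SeedSet]:
    """Commit a swap: sigma arrays first, then seeds, OM matrices, OCM."""
    q, i, j = swap.seed_index, swap.one_pos, swap.star_pos
    # sigma arrays are updated before the seed so update_sigma still sees
    # the pre-swap patterns
    new_total = state.total_oc
    for r in range(S.k):
        key = _canonical(r, q)
        new_sig = update_sigma(state, key, swap, S)
        new_oc = oc_from_sigma(new_sig)
        new_total += new_oc - state.ocm[key]
        state.sigma[key] = new_sig
        state.ocm[key] = new_oc
    if new_total != swap.candidate_oc:
        raise ValueError("swap is inconsistent with the current state")
    if new_total >= state.total_oc:
        raise ValueError("refusing a swap that does not strictly decrease OC")
    state.total_oc = new_total

    pat = list(S[q].pattern)
    pat[i], pat[j] = pat[j], pat[i]
    S.seeds[q] = Seed("".join(pat))

    # refresh the OM rows/columns the swap touched
    for r in range(S.k):
        a_idx, b_idx = _canonical(r, q)
        m = state.om[a_idx, b_idx]
        va = np.frombuffer(S[a_idx].pattern.encode(), dtype=np.uint8) == ord("1")
        vb = np.frombuffer(S[b_idx].pattern.encode(), dtype=np.uint8) == ord("1")
        if q == b_idx:
            for c in (i, j):
                both1 = va & vb[c]
                both0 = ~va & ~vb[c]
                m[:, c] = both1.astype(np.int8) - (~both1 & ~both0).astype(np.int8)
        if q == a_idx:
            for rr in (i, j):
                both1 = va[rr] & vb
                both0 = ~va[rr] & ~vb
                m[rr, :] = both1.astype(np.int8) - (~both1 & ~both0).astype(np.int8)
    return state, S


@dataclass
class DesignConfig:
    """Parameters of one design run.

    ``lengths`` is either an explicit list of k seed lengths or a
    ``(lmin, lmax)`` range, in which case lengths are spread evenly
    across the range (ties toward the longer end).  ``N`` and ``p`` fix
    the Bernoulli model used for the final sensitivity evaluation;
    ``select_by`` picks the winning restart either by lowest OC
    (default, cheap) or by highest sensitivity of the finalists.
    """

    k: int
    w: int
    lengths: Sequence[int] | tuple[int, int]
    N: int = 64
    p: float = 0.70
    restarts: int = 10
    rng_seed: int = 0
    select_by: Literal["oc", "sensitivity"] = "oc"
    state_budget: int = DEFAULT_STATE_BUDGET

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        lengths = self.resolved_lengths()
        if any(l < self.w for l in lengths):
            raise ValueError(f"all lengths must be >= weight {self.w}, got {lengths}")

    def resolved_lengths(self) -> list[int]:
        lengths = list(self.lengths)
        if len(lengths) == self.k:
            return lengths  # for k == 2 the range reading gives the same list
        if len(lengths) == 2:
            return resolve_lengths(self.k, lengths[0], lengths[1])
        raise ValueError(
            f"lengths must be a (lmin, lmax) range or an explicit list of k={self.k} values"
        )


def resolve_lengths(k: int, lmin: int, lmax: int) -> list[int]:
    """Spread k seed lengths evenly across [lmin, lmax], ties toward lmax."""
    if lmin > lmax:
        raise ValueError(f"empty length range [{lmin}..{lmax}]")
    if k == 1:
        return [lmax]
    step = (lmax - lmin) / (k - 1)
    return [lmax - int(np.floor((k - 1 - i) * step)) for i in range(k)]


def random_seed_set(config: DesignConfig, rng: np.random.Generator) -> SeedSet:
    """Random starting set: 1s at both ends, interior 1s placed uniformly."""
    seeds = []
    for l in config.resolved_lengths():
        w = config.w
        if l == w:
            seeds.append(contiguous_seed(w))
            continue
        if w < 2:
            raise ValueError(f"cannot place 1s at both ends of a length-{l} seed of weight {w}")
        interior = rng.choice(l - 2, size=w - 2, replace=False) + 1
        pat = ["*"] * l
        pat[0] = pat[-1] = "1"
        for t in interior:
            pat[t] = "1"
        seeds.append(Seed("".join(pat)))
    return SeedSet(seeds, require_uniform_weight=True)


@dataclass
class DesignReport:
    """Everything needed to reproduce and audit a design run."""

    config: DesignConfig
    restart_initial_oc: list[int] = field(default_factory=list)
    restart_final_oc: list[int] = field(default_factory=list)
    best_restart: int = -1
    best_set: SeedSet | None = None
    best_oc: int = -1
    sensitivity: float | None = None
    sensitivity_percent: str | None = None
    oc_trace: list[int] = field(default_factory=list)
    wall_seconds: float = 0.0


def design(config: DesignConfig) -> DesignReport:
    """Multi-restart hill climbing: random start, climb, keep the best.

    Restarts are independent; the winner is the restart with the lowest
    final OC, or, with ``select_by='sensitivity'``, the finalist with the
    highest exact sensitivity at ``(N, p)``.  If the sensitivity
    evaluation of a finalist exceeds the automaton state budget the run
    falls back to OC selection with a logged warning.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.rng_seed)
    model = BernoulliModel(config.N, config.p)
    report = DesignReport(config=config)
    finalists: list[tuple[SeedSet, list[int]]] = []
    for r in range(config.restarts):
        start = random_seed_set(config, rng)
        final, trace = climb(start)
        finalists.append((final, trace))
        report.restart_initial_oc.append(trace[0])
        report.restart_final_oc.append(trace[-1])
        logger.info("restart %d: OC %d -> %d after %d swaps", r, trace[0], trace[-1], len(trace) - 1)

    if config.select_by == "sensitivity":
        try:
            sens = [
                sensitivity(s, model, state_budget=config.state_budget) for s, _ in finalists
            ]
            best = int(np.argmax(sens))
        except StateBudgetExceeded:
            logger.warning(
                "sensitivity selection exceeded the automaton state budget; "
                "falling back to OC selection"
            )
            best = int(np.argmin(report.restart_final_oc))
    else:
        best = int(np.argmin(report.restart_final_oc))

    report.best_restart = best
    report.best_set, report.oc_trace = finalists[best]
    report.best_oc = report.restart_final_oc[best]
    try:
        report.sensitivity = sensitivity(report.best_set, model, state_budget=config.state_budget)
        from .sensitivity import format_percent

        report.sensitivity_percent = format_percent(report.sensitivity)
    except StateBudgetExceeded:
        logger.warning("final sensitivity evaluation exceeded the state budget; omitted")
    report.wall_seconds = time.perf_counter() - t0
    return report
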