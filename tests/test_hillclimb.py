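"""Hill climbing: incremental bookkeeping vs from-scratch oracles, climbs, design."""

import numpy as np
import pytest

from spacedseeds import (
    BernoulliModel,
    DesignConfig,
    SeedSet,
    SwapCandidate,
    apply_swap,
    best_swap,
    climb,
    contiguous_seed,
    design,
    init_state,
    oc_from_sigma,
    oc_set,
    parse_seed,
    random_seed_set,
    resolve_lengths,
    sensitivity,
    sigma_array,
    update_sigma,
)

from conftest import make_random_set, naive_oc_set


def legal_swaps(S):
    for q in range(S.k):
        sq = S[q]
        for i in [t for t in sq.ones if 0 < t < sq.length - 1]:
            for j in sq.stars:
                yield q, i, j


def swapped_patterns(S, q, i, j):
    pats = list(S.patterns)
    p = list(pats[q])
    p[i], p[j] = p[j], p[i]
    pats[q] = "".join(p)
    return pats


def test_init_state_matches_definitions():
    S = SeedSet(["1*11", "1**1*1"])
    st = init_state(S)
    assert st.ocm[0, 1] == 20
    assert st.total_oc == oc_set(S)
    om = st.om[0, 1]
    assert om.shape == (4, 6)
    assert om[0, 0] == 1 and om[1, 1] == 0 and om[0, 1] == -1
    assert init_state(SeedSet(["1"])).total_oc == 2


def test_init_state_random_sets_match_naive_oc(rng):
    for _ in range(20):
        S = make_random_set(rng, k=int(rng.integers(1, 5)), w=4, lmin=4, lmax=10)
        assert init_state(S).total_oc == naive_oc_set(S.patterns)


def test_oc_from_sigma():
    assert oc_from_sigma([1, 0, 2, 1, 1, 2, 0, 1, 1]) == 20
    assert oc_from_sigma([0]) == 1


def test_oc_from_sigma_random(rng):
    for _ in range(20):
        sig = rng.integers(0, 21, size=int(rng.integers(1, 15)))
        assert oc_from_sigma(sig.tolist()) == sum(2**s for s in sig)


def test_update_sigma_matches_from_scratch(rng):
    """Every pair's predicted sigma equals recomputation on the swapped seeds."""
    for _ in range(60):
        S = make_random_set(rng, k=int(rng.integers(1, 4)), w=int(rng.integers(3, 6)), lmin=5, lmax=12)
        st = init_state(S)
        swaps = list(legal_swaps(S))
        if not swaps:
            continue
        q, i, j = swaps[rng.integers(len(swaps))]
        cand = SwapCandidate(q, i, j, candidate_oc=-1)
        after = [parse_seed(p) for p in swapped_patterns(S, q, i, j)]
        for r in range(S.k):
            key = (min(r, q), max(r, q))
            got = update_sigma(st, key, cand, S)
            want = sigma_array(after[key[0]], after[key[1]])
            assert got == want, (S.patterns, (q, i, j), key)


def test_update_sigma_self_pair_example():
    S = SeedSet(["1*11"])
    st = init_state(S)
    got = update_sigma(st, (0, 0), SwapCandidate(0, 2, 1, -1), S)
    s2 = parse_seed("11*1")
    assert got == sigma_array(s2, s2)


def test_update_sigma_is_an_involution(rng):
    """Predicting a swap and then its inverse returns the original sigma."""
    for _ in range(10):
        S = make_random_set(rng, k=2, w=4, lmin=6, lmax=9)
        st = init_state(S)
        q, i, j = next(iter(legal_swaps(S)))
        swapped = SeedSet([parse_seed(p) for p in swapped_patterns(S, q, i, j)])
        st2 = init_state(swapped)
        back = SwapCandidate(q, j, i, candidate_oc=-1)  # star positions are interior
        for r in range(S.k):
            key = (min(r, q), max(r, q))
            assert update_sigma(st, key, SwapCandidate(q, i, j, -1), S) == st2.sigma[key]
            assert update_sigma(st2, key, back, swapped) == st.sigma[key]


def test_update_sigma_rejects_illegal_positions():
    S = SeedSet(["1*11"])
    st = init_state(S)
    with pytest.raises(ValueError):
        update_sigma(st, (0, 0), SwapCandidate(0, 0, 1, -1), S)  # endpoint 1
    with pytest.raises(ValueError):
        update_sigma(st, (0, 0), SwapCandidate(0, 2, 3, -1), S)  # star_pos holds a 1


def test_best_swap_matches_exhaustive_oracle(rng):
    """candidate_oc equals the minimum OC over all single swaps, or None at optima."""
    for _ in range(40):
        S = make_random_set(rng, k=int(rng.integers(1, 4)), w=int(rng.integers(3, 6)), lmin=5, lmax=12)
        st = init_state(S)
        options = [
            (naive_oc_set(swapped_patterns(S, q, i, j)), q, i, j) for q, i, j in legal_swaps(S)
        ]
        cand = best_swap(st, S)
        improving = [o for o in options if o[0] < st.total_oc]
        if not improving:
            assert cand is None
        else:
            best = min(improving)
            assert cand.candidate_oc == best[0]
            assert (cand.seed_index, cand.one_pos, cand.star_pos) == best[1:]


def test_best_swap_singleton_contiguous():
    """1111 in a singleton set: no swap exists (no stars), so it is a local optimum."""
    S = SeedSet(["1111"])
    assert best_swap(init_state(S), S) is None


def test_best_swap_leaves_state_unmodified(rng):
    S = make_random_set(rng, k=2, w=4, lmin=6, lmax=9)
    st = init_state(S)
    before = (st.total_oc, {k: list(v) for k, v in st.sigma.items()}, dict(st.ocm))
    best_swap(st, S)
    assert st.total_oc == before[0]
    assert {k: list(v) for k, v in st.sigma.items()} == before[1]
    assert st.ocm == before[2]


def test_apply_swap_equals_from_scratch_state(rng):
    """After any sequence of applied swaps the state matches init_state exactly."""
    for _ in range(15):
        S = make_random_set(rng, k=int(rng.integers(1, 4)), w=int(rng.integers(3, 6)), lmin=5, lmax=12)
        st = init_state(S)
        prev = st.total_oc
        while (cand := best_swap(st, S)) is not None:
            apply_swap(st, S, cand)
            assert st.total_oc < prev  # strict decrease at every accepted swap
            prev = st.total_oc
            fresh = init_state(S)
            assert st.total_oc == fresh.total_oc
            assert st.sigma == fresh.sigma
            assert st.ocm == fresh.ocm
            for key in fresh.om:
                assert (st.om[key] == fresh.om[key]).all()
        for s in S:
            assert s.pattern[0] == "1" and s.pattern[-1] == "1"


def test_climb_is_idempotent_and_decreasing(rng):
    for _ in range(10):
        S = make_random_set(rng, k=2, w=5, lmin=9, lmax=9)
        final, trace = climb(S)
        assert trace[0] == oc_set(S)
        assert trace[-1] == oc_set(final)
        assert all(a > b for a, b in zip(trace, trace[1:]))
        again, trace2 = climb(final)
        assert again == final and len(trace2) == 1


def test_climb_singleton_reaches_exhaustive_optimum():
    """k=1, w=4, l=7: greedy from every start vs all C(5,2) interior placements."""
    import itertools

    shapes = []
    for pair in itertools.combinations(range(1, 6), 2):
        pat = ["*"] * 7
        pat[0] = pat[-1] = "1"
        for t in pair:
            pat[t] = "1"
        shapes.append("".join(pat))
    all_ocs = {s: naive_oc_set([s]) for s in shapes}
    global_min = min(all_ocs.values())
    reached = set()
    for start in shapes:
        final, trace = climb(SeedSet([start]))
        assert trace[-1] <= all_ocs[start]
        reached.add(trace[-1])
    # greedy from the best start must of course realize the global optimum
    assert global_min in reached


def test_resolve_lengths():
    assert resolve_lengths(1, 14, 27) == [27]
    assert resolve_lengths(2, 6, 7) == [6, 7]
    spread = resolve_lengths(16, 14, 27)
    assert len(spread) == 16 and spread[0] == 14 and spread[-1] == 27
    assert all(a <= b for a, b in zip(spread, spread[1:]))
    assert resolve_lengths(3, 5, 5) == [5, 5, 5]
    with pytest.raises(ValueError):
        resolve_lengths(2, 7, 6)


def test_random_seed_set_reproducible_and_valid():
    cfg = DesignConfig(k=3, w=5, lengths=(8, 12), rng_seed=11)
    a = random_seed_set(cfg, np.random.default_rng(7))
    b = random_seed_set(cfg, np.random.default_rng(7))
    assert a == b
    for s, l in zip(a, cfg.resolved_lengths()):
        assert s.weight == 5 and s.length == l


def test_random_seed_set_contiguous_when_length_equals_weight():
    cfg = DesignConfig(k=2, w=4, lengths=[4, 4], rng_seed=0)
    S = random_seed_set(cfg, np.random.default_rng(0))
    assert S.patterns == ["1111", "1111"]


def test_random_seed_set_interior_placement_uniform(rng):
    """w=4, l=6: the C(4,2)=6 interior placements should be equally likely."""
    from itertools import combinations
    from scipy.stats import chisquare

    cfg = DesignConfig(k=1, w=4, lengths=[6], rng_seed=0)
    counts = {frozenset(c): 0 for c in combinations(range(1, 5), 2)}
    for _ in range(6000):
        s = random_seed_set(cfg, rng)[0]
        counts[frozenset(t for t in s.ones if 0 < t < 5)] += 1
    assert chisquare(list(counts.values())).pvalue > 0.001


def test_design_deterministic_given_seed():
    cfg = DesignConfig(k=2, w=4, lengths=(6, 7), N=16, p=0.7, restarts=1, rng_seed=3)
    r1, r2 = design(cfg), design(cfg)
    assert r1.best_set == r2.best_set and r1.best_oc == r2.best_oc


def test_design_beats_contiguous_baseline():
    """A designed single seed of weight 11 outperforms BLAST's contiguous seed."""
    cfg = DesignConfig(k=1, w=11, lengths=[18], N=64, p=0.70, restarts=3, rng_seed=1)
    report = design(cfg)
    model = BernoulliModel(64, 0.70)
    baseline = sensitivity(contiguous_seed(11), model)
    assert report.sensitivity is not None
    assert report.sensitivity > baseline
    assert report.best_oc <= min(report.restart_final_oc)


def test_design_small_instance_restarts_bookkeeping():
    cfg = DesignConfig(k=2, w=4, lengths=(6, 7), N=16, p=0.7, restarts=4, rng_seed=9)
    report = design(cfg)
    assert len(report.restart_final_oc) == 4
    assert all(f <= i for i, f in zip(report.restart_initial_oc, report.restart_final_oc))
    assert report.best_oc == min(report.restart_final_oc)
    assert report.sensitivity_percent is not None


def test_design_select_by_sensitivity():
    cfg = DesignConfig(k=1, w=4, lengths=[7], N=12, p=0.6, restarts=3, rng_seed=2,
                       select_by="sensitivity")
    report = design(cfg)
    model = BernoulliModel(12, 0.6)
    # the winner's sensitivity is maximal among what any restart could offer
    assert report.sensitivity == pytest.approx(sensitivity(report.best_set, model), rel=1e-12)


def test_design_config_validation():
    with pytest.raises(ValueError):
        DesignConfig(k=0, w=4, lengths=[5])
    with pytest.raises(ValueError):
        DesignConfig(k=1, w=6, lengths=[5])
    with pytest.raises(ValueError):
        DesignConfig(k=1, w=4, lengths=[5], restarts=0)
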