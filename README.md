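# spacedseeds

Design and exact evaluation of multiple spaced seeds for similarity search.

## The problem

Seed-and-extend similarity search (BLAST and its descendants) only inspects
alignments that contain a *hit* of a seed. A **spaced seed** is a template
over `{1, *}` — `1` marks a position that must be a match, `*` a don't-care —
so BLAST's default word is the contiguous seed `11111111111` while
PatternHunter uses the spaced seed `111*1**1*1**11*111` of the same weight.
Under the Bernoulli alignment model, an alignment is a random 0/1 region `R`
of length `N` whose positions are matches independently with probability `p`
(the *similarity*). A seed `s` hits `R` at offset `i` if every 1-position `j`
of `s` faces a match (`s[j] = 1 ⇒ R[i+j] = 1`); a seed set
`S = {s₁, …, s_k}` hits when any member does. The **sensitivity** of `S` is
the probability that it hits `R`. At equal weight — hence equal random-hit
rate — well-spread multiple seeds are dramatically more sensitive than a
contiguous word, so the design problem is: given `k`, weight `w` and seed
lengths, place the 1s to maximize sensitivity.

Sensitivity is expensive to compute and the design problem is hard, so the
practical route optimizes **overlap complexity** instead. For each of the
`ℓᵢ + ℓⱼ − 1` relative placements of a seed pair, let `σ` count positions
where both seeds have a `1`; then

    OC(sᵢ, sⱼ) = Σ_shifts 2^σ,      OC(S) = Σ_{i ≤ j} OC(sᵢ, sⱼ)

(self-pairs included). Low OC is strongly correlated with high sensitivity
and is polynomial-time computable. This package

* computes OC naively and bit-parallel (seed bitmasks, shift-AND, block
  popcount tables) — the two routes agree exactly on every input;
* optimizes seed sets by **incremental hill climbing**: the single `(1, *)`
  swap that most reduces OC is found by maintaining per-pair agreement
  matrices (`OM`), per-shift coincident-1 counts (`σ`) and pairwise OC values
  (`OCM`), so a candidate swap is scored by local corrections rather than a
  full recomputation; random restarts wrap the greedy descent;
* evaluates sensitivity **exactly**, by compiling the hit predicate into a
  deterministic automaton over `{0, 1}` and pushing the Bernoulli state
  distribution forward `N` steps; contiguous seeds have an independent O(N)
  run-occurrence recurrence as a cross-check.

## Worked example

Evaluate the two classic weight-11 seeds on a region of length 64 at 70%
similarity:

```
$ printf '11111111111\n' > blast.txt
$ spacedseeds sensitivity blast.txt --N 64 --p 0.70 --percent
30.0196
$ printf '111*1**1*1**11*111\n' > ph.txt
$ spacedseeds sensitivity ph.txt --N 64 --p 0.70 --percent
46.7122
```

The contiguous BLAST word hits only 30.02% of such regions; PatternHunter's
spaced seed of the same weight hits 46.71% — same specificity, half again the
sensitivity, purely from the placement of the 1s.

Designing a 4-seed set of weight 11 (lengths spread over 14..27) takes a few
seconds:

```
$ spacedseeds design --k 4 --w 11 --lengths 14:27 --N 64 --p 0.70 \
      --restarts 5 --rng-seed 1 -o demo.txt
# k=4 w=11 lengths=[14, 19, 23, 27] N=64 p=0.7 restarts=5 rng_seed=1 select_by=oc
restart	0	14665	13061
restart	1	15483	13079
restart	2	14522	13081
restart	3	14583	13054
restart	4	15144	13089
best_restart	3
best_oc	13054
sensitivity_percent	75.9931
1111*1*111*111
1111**1**1*1**1*111
111*1**1*****11**1*1*11
11*11***1**1***1****1***111
```

Each `restart` line reports initial and final OC of one independent climb;
the winner (lowest final OC) is re-evaluated exactly: the 4-seed set hits
75.99% of regions, versus 30.02% for the contiguous seed of equal weight.
With `--k 16` the same procedure exceeds 93%. The `oc` subcommand prints
`OC(S)` with the per-pair matrix, and `fixtures` writes reproducible random
seed files.

## Layout

| module | contents |
| --- | --- |
| `spacedseeds.seed_model` | `Seed`/`SeedSet`, parsing, bitmasks, seed-file I/O |
| `spacedseeds.overlap_complexity` | `σ` arrays, naive and bit-parallel OC, popcount tables |
| `spacedseeds.sensitivity` | hit automaton, exact Bernoulli DP, run recurrence |
| `spacedseeds.hillclimb` | incremental `OM/σ/OCM` state, best-swap scan, climbs, restarts |
| `spacedseeds.cli` | `oc`, `sensitivity`, `design`, `fixtures` subcommands |

See `docs/methods.md` for the model details, numerical choices and known
limitations.
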