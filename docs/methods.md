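# Methods

## Model and definitions

A spaced seed is a string over `{1, *}` that starts and ends with `1`
(a don't-care at either end never changes the hit set, so it is excluded
by construction). Weight `w` = number of 1s, length `ℓ` = number of
characters. A multiple seed is an ordered set `S = {s₁, …, s_k}`; in
design mode all members share one weight, so that the set has a uniform
random-hit rate and sensitivities are comparable; evaluation accepts
mixed weights.

Alignments follow the Bernoulli model: a region `R ∈ {0,1}^N` with
i.i.d. match probability `p`. `S` hits `R` if some seed aligns all its
1s with 1s of `R` at some offset. Sensitivity is `P(S hits R)`. The
package does not model Markov dependence, indels, or homology structure;
see Limitations.

## Overlap complexity

For a pair `(sᵢ, sⱼ)` and each of the `ℓᵢ + ℓⱼ − 1` relative placements,
`σ` counts coincident 1s; `OC(sᵢ, sⱼ) = Σ 2^σ` and
`OC(S) = Σ_{i≤j} OC(sᵢ, sⱼ)`, self-pairs included. The index convention
for `σ_ij[r]` is the distance between the right end of `s_j` and the
left end of `s_i`; since OC is a sum over all shifts, only the multiset
of `σ` values matters to the objective.

Two implementations exist deliberately: a character-level one
(`oc_pair`) that follows the definition, and a bit-parallel one
(`oc_pair_fast`) that interprets seeds as integers (leftmost character
most significant, `1**11 → 10011₂ = 19`), ANDs shifted masks and counts
bits through a precomputed block popcount table. The 16-bit table is the
default (fastest in practice); the 8-bit table is kept for parity
testing. Masks are arbitrary-precision Python integers, so seeds longer
than 64 positions are fully supported, and all `Σ 2^σ` arithmetic is
exact integer arithmetic.

## Hill climbing

The optimizer repeatedly applies the best single `(1, *)` swap inside
one seed until no swap strictly reduces `OC(S)`. Choices fixed here:

* **Strict descent.** Equal-OC moves are rejected. OC is a positive
  integer, so termination is immediate; plateau walks would require a
  cycle-avoidance mechanism for no observed benefit.
* **Endpoint protection.** Positions `0` and `ℓ−1` are never offered for
  swapping, preserving the start/end-with-1 convention (weight and
  length are invariant under swaps anyway).
* **Tie-breaking.** Among equally best swaps, the first in scan order
  (ascending seed index, then 1-position, then *-position) wins, making
  climbs deterministic given the starting set.

Candidate swaps are scored incrementally. The state keeps, per pair
`i ≤ j`: the agreement matrix `OM` (+1 both 1s, 0 both stars, −1
mixed), the `σ` array (diagonal sums of the 1-entries of `OM`), and the
pair OC (`OCM`). Removing the 1 at position `i` of a seed decrements
`σ` on every diagonal where the partner seed has a facing 1; adding a 1
at `j` increments symmetrically — `update_sigma` produces the post-swap
`σ` of a pair in time linear in seed length without mutating anything,
with the self-pair handled separately because the swap then changes both
the row and the column seed. After the best swap is chosen, `σ` arrays
are updated before the seed string (so the same prediction routine
applies), then `OM` rows/columns and `OCM`.

The best-swap scan evaluates all candidates of a seed against all pairs
in one vectorized pass: with `P[r] = 2^σ[r]`, moving a 1 from `i` to `j`
changes the pair OC by `−½·ΣP[D_i] + ΣP[A_j] − ½·ΣP[D_i ∩ A_j]`, where
`D_i`/`A_j` are the diagonals hit by the removal/addition; the self-pair
delta is obtained from the autocorrelation of the swapped 0/1 vector.
Every quantity is an integer below 2⁵³, so the float arithmetic is
exact; the winning candidate is re-scored through the integer
`update_sigma` path and both routes are asserted equal. Test suites
verify the incremental state field-for-field against from-scratch
recomputation after randomized swap sequences, and the chosen swap
against exhaustive enumeration of all swaps scored by a naive OC oracle.

### Restarts and starting sets

A starting seed has 1s at both ends and its `w−2` interior 1s placed
uniformly at random (chi-square-tested in the suite). The default
schedule is 10 independent restarts selected by lowest final OC;
selection by exact sensitivity of the finalists is available
(`select_by="sensitivity"`) but off by default because evaluating every
finalist of a heavy multiple seed costs far more than the climbs
themselves. When lengths are given as a range `[ℓmin..ℓmax]`, the `k`
lengths are spread evenly across the range with ties resolved toward
`ℓmax`. These schedule details are this package's own choices.

## Exact sensitivity

The hit predicate is compiled to a complete DFA over `{0,1}` with one
absorbing hit state. A state records, per seed, the bitmask of prefix
lengths compatible with the region suffix read so far; reading symbol
`c` extends prefix `j` to `j+1` iff `s[j] = *` or `c = 1`, and
completing any seed is a hit. States are deduplicated during BFS
(a subset construction over seed-compatible prefixes in the spirit of
Aho–Corasick), and the sensitivity is the mass in the hit state after
`N` forward steps of the transition structure.

* **State budget.** Construction aborts with an explicit error at
  2·10⁶ states by default (configurable). Spaced seeds can in principle
  force exponentially many states; the shapes used here stay modest
  (279 states for the weight-11 PatternHunter seed; ≈2.3·10⁵ for a
  designed 16-seed weight-11 set).
* **Linear-space probabilities.** With `N` at most a few hundred and
  `p` bounded away from 0 and 1, no intermediate mass approaches the
  underflow threshold, so no log-space transform is used.
* **Contiguous seeds** run through the same general path; the
  first-occurrence recurrence `q_n = q_{n−1} − (1−p)·p^w·q_{n−w−1}`
  (with `q_n = 1` for `n < w`, `q_w = 1 − p^w`) is kept as an
  independent O(N) cross-check oracle, not a fast path — the two routes
  agree to better than 10 significant digits wherever compared.
* **Reporting.** Table mode prints percentages with 4 decimals, rounded
  half-even; raw mode prints the full double.

The suite validates the DP against exhaustive enumeration of all `2^N`
regions for small `N` (to 12 significant digits) and checks monotonicity
in `N`, in `p`, and under seed-set inclusion.

## Problem sizes exercised

Unit and property tests run on seeds of weight ≤ 18 and length ≤ 30,
exhaustive automaton checks at `N ≤ 14`, and full-scale design at
`k = 16`, `w = 11`, lengths 14..27, `N = 64`, `p = 0.70` with 10
restarts — the heaviest published single-table setting — where designed
sets reach ≥ 92–93% sensitivity versus 30.02% for the contiguous
baseline. Heavier weight-28 design runs (minutes, not seconds) use the
same code paths and are exercised only through the weight-28 contiguous
evaluations.

## What the random starting sets do and do not emulate

The generator draws uniform interior 1-placements, which is exactly the
search space of the optimizer — there is no attempt to mimic biological
sequence composition, because under the Bernoulli model seed quality
depends only on `(N, p)` and the seed shapes. Passing tests therefore
certify the combinatorial optimization and the exact evaluation; they do
not certify that the Bernoulli model describes any particular genome
comparison.

## Known limitations

* Local optima: greedy descent with restarts carries no global
  guarantee; published multi-seed sensitivities depend on the exact
  deposited seed sets and restart schedules, so equally good but not
  identical sets should be expected from different seeds/schedules.
* Seeds are compared only at equal weight; cross-length or cross-weight
  comparison needs a different objective.
* Bernoulli model only; no transition-constrained or vector seeds; no
  integration with an aligner's extend stage.
* OC is a surrogate: minimizing it does not always maximize
  sensitivity, it is merely strongly correlated.
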