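# Methods

## Model

A minimizer (w, k, O) selects in every window of w consecutive k-mers
the position of the smallest k-mer under the strict total order O,
preferring the leftmost position on ties.  All coordinates are 0-based;
a k-mer's position is its start; a window is a half-open run of w
consecutive k-mer starts; a *context* is w+1 consecutive k-mers (two
overlapping windows) and is *charged* when its two windows select
different positions.  On a break-free sequence the number of selected
positions equals the number of charged contexts plus one, an identity
the package maintains exactly per fragment and tests by fuzzing.

Orders are realized as (layer rank, hash, code) triples: k-mers in an
earlier layer of a priority list compare below everything later or
outside, and within a stratum a SplitMix64-style avalanche hash of the
packed k-mer code (seeded) decides, with the packed code itself as the
final tie-break.  This gives a reproducible, near-uniform random order
without materializing a permutation of sigma^k elements; hash
collisions on 64 bits are negligible at any practical scale, and the
code tie-break keeps the order a strict total order regardless.

The energy of a context c with u(c) distinct k-mers is E(c) = 2/u if
the last k-mer occurs exactly once within c, else 1/u — the probability
that c is charged under a uniformly random order.  "Distinct count" and
"last k-mer unique within the context" are the semantics confirmed by
an exhaustive-permutation oracle in the test suite (all orders of the
distinct k-mers of a context, charged fraction compared exactly).
Aggregates over all contexts: E0 (initial energy), D (summed deficit
below the 2/(w+1) baseline), X (summed surplus above it).  E0 is
computed in O(n) with a previous-occurrence sliding count.

A polar set of slackness s has all member occurrences pairwise at least
ceil((1−s)·w) bases apart ("at least" inclusive; the product is rounded
to 9 decimals before the ceiling to keep 0.6·w·10 = 6, not 7, under
binary floating point).  Layered sets exempt occurrences *covered* by
two earlier-layer occurrences l < t < h with h − l ≤ w (strict
inequalities).  Spacing applies to any occurrence pair, including two
occurrences of the same k-mer and occurrences of covered members; the
validator and the construction filters agree on this reading, so every
built set passes validation by construction.

Link energy: consecutive uncovered occurrences at gap l ≤ w contribute
2l/(w+1) − 1.  The aggregate route L = 2·Acov/(w+1) − Aele − Aseg
(covered-context count, uncovered-occurrence count, segment count) is
evaluated in integer arithmetic scaled by (w+1) and asserted equal to
the pairwise sum.  Segments are maximal runs of occurrences at
consecutive gaps ≤ w — defined on occurrence gaps, not on context
overlaps, because context ranges remain contiguous at gap w+1 where no
link exists, and using them would add spurious energy.

## Boundary handling (exact, not asymptotic)

The density sandwich 1 + E0 − X − L ≤ E[#selected] ≤ 1 + E0 + D − L is
an interior statement; within w bases of a fragment end the charged-
context accounting changes by O(1) per fragment, and a Monte-Carlo
check over random compatible orders can detect the discrepancy.  The
package therefore resolves end effects exactly rather than
asymptotically:

- `LinkStats.Acov` counts only contexts that exist (clipped to each
  fragment's context range); `acov_unclipped` keeps the idealized count,
  with which the formula identity is exact everywhere.
- The upper bound uses 2·Acov/(w+1) − Aele − Aseg with the clipped
  Acov: within any segment the charged-context count is at most d + 1
  for every order, and existing-context energies sum to at least
  2·n_ctx/(w+1) after elevating savers.
- The lower bound uses 2·Acov/(w+1) − ea_min, where ea_min counts the
  charges guaranteed for *every* compatible order: members with an
  in-fragment "solo" window (a window they occupy alone) are always
  selected, selected positions are non-decreasing as windows slide, and
  the entering/leaving charge contexts are certain when they exist.
  Away from fragment ends ea_min = Aele + Aseg and both credits equal L.
- Links never span a break (no window does), and coverage flanks must
  lie in the covered occurrence's fragment; occurrences in fragments
  too short for a single window are excluded from the statistics.

The `LinkedBlocks` ledger used inside the builder keeps the unclipped
convention (its aggregates equal a from-scratch recomputation over its
stored positions, fuzz-tested over 10^4 operations); it only drives the
monotonic accept/reject sign, for which boundary constants are
irrelevant.

## Construction heuristic

Per round: fix an offset o, visit valid k-mer starts t ≡ o (mod w) in a
seeded shuffled order, and admit the k-mer at t unless it (a) was
already visited this round or sits in an earlier layer, (b) occurs more
often than the round's frequency cutoff, (c) has no uncovered
occurrence, (d) self-collides (an uncovered occurrence under the
spacing threshold from any other occurrence of the same k-mer), or
(e) has an uncovered occurrence under the threshold from an
earlier-layer occurrence.  Admission evicts current members with a
conflicting occurrence pair (at least one side uncovered).  In
monotonic rounds the staged evict-and-insert is applied to the energy
ledger first and rolled back unless the total link energy strictly
increases.  At the end of a round, members none of whose uncovered
occurrences has a link are pruned (their removal cannot destroy
anyone else's links), and the surviving k-mers become the next layer.

Occurrence lists come from a suffix-array index (numpy prefix doubling,
O(n log^2 n), plus a Kasai LCP pass); a query scans outward from
isa[t] while LCP ≥ k, costing O(occurrences).  Conflict and coverage
queries use bisection over sorted occurrence arrays and the
linked-blocks structure (block width floor(w/2), at most one selected
location per block — guaranteed because uncovered occurrences are
pairwise further than w/2 apart).

Defaults mirror the recommended recipe: 7 rounds, last 2 monotonic,
slackness s = 0.4, frequency cutoff covering 85% of positions in round
1 rising linearly to 95% in the last round.  Offsets are drawn without
replacement while rounds ≤ w (with replacement otherwise).  Per-round
"first encounter" deduplication is per round, not global: each round
re-shuffles a fresh congruence class.  All randomness flows from the
single `HeuristicConfig.seed`.

## Synthetic data

The generators produce the regimes the theory distinguishes, with no
external downloads:

- `uniform` — i.i.d. characters over sigma ∈ {2, 3, 4} letters; the
  random-minimizer baseline has expected density 2/(w+1) here, and at
  (n = 10^6, w = 10, k = 15) the average energy deficit and surplus per
  context are below 10^−7.
- `periodic` — period-w strings with w distinct k-mers: every context
  is an energy saver (E = 1/w), the adversarial extreme.
- `planted_perfect` — a uniform draw in the short regime
  n < ε·w·σ^k/2 (ε defaults to 0.01, a warning outside it), where
  fixed-interval sampling is a zero-slack polar set with probability
  ≥ 1 − ε and the compatible minimizer is perfect.
- `repeat_mosaic` — tandem, lightly mutated repeat units producing
  frequent k-mers that exercise the self-collision and frequency
  filters.

What these do *not* emulate: real genomes' long-range duplications,
GC/composition skew, and centromeric satellite structure.  Passing
tests on these fixtures validate the algebraic identities, the bound
logic and the construction contracts at desk scale; absolute density
numbers on real references (which are more repetitive) will differ,
with repeat-rich regions degrading toward the random baseline.

## Problem sizes and tolerances

Test and acceptance workloads are sized for a laptop-class single CPU:
density-factor calibration at n = 10^6 over 20 seeds, energy aggregates
at n = 10^6, end-to-end builds at n = 10^5 (w = 10, k = 15), fuzz
suites at n ≤ 4 000.  Monte-Carlo identities are asserted within 3
standard errors; integer-scaled identities exactly; floating-point
formula equivalence at 10^−12.  The heuristic's per-round cost is
within a constant of the suffix-array query volume and scales roughly
linearly in n (soft-checked in the suite); the index build is the
asymptotic bottleneck.

## Known limitations

- Forward strand only; no canonical (reverse-complement) k-mers.
- Alphabet is mapped to at most 4 DNA letters (2-bit-style packing,
  k ≤ 31 at sigma = 4); proteins would need a wider code path.
- The exact optimum (the integer program over the k-mer collision
  graph) is out of scope; only the greedy/monotonic heuristics are
  provided.
- Density is reported over valid k-mer positions in fragments that
  admit at least one window; window-less fragments are skipped.
- s ≥ 1/2 is rejected outright; the upper-bound-only regime it would
  allow is not implemented.
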