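# Methods

## The descriptor model

A motif is a 5'→3' list of element occurrences (the motif map) that tiles a
contiguous substring: consecutive occurrence intervals abut, and an
occurrence may be empty (an all-wildcard element matching nothing). Helices
appear twice, `h<k>` for the 5' strand and `h<k>'` for the 3' strand, with
no restriction on interleaving — `h1 h2 h1' h2'` is a pseudoknot, and the
bundled HDV-like fixture interleaves two pairs of its four helices.

Single-strand patterns are IUPAC classes plus `*` (one arbitrary base or the
empty string). Helix strands are column-aligned; the 3' strand is written
3'→5' so column *j* of both strands pair with each other, and the helix is
matched zipping from the outside in. Variable helix length is expressed
solely through wildcard columns (`*` on **both** strands; mixed columns are
rejected at parse time because no consistent per-strand length bound exists
for them) and through bulge insertions.

Distortion budgets are per element: `m` mismatches (a base outside its
class; counted across both helix strands against one shared budget), `r`
mispairs (an aligned column outside the pair set), `i` insertions. An
insertion consumes one text base at an internal junction between two pattern
tokens; flanking insertions are disallowed because they are
indistinguishable from slack belonging to the neighbouring element. In
helices an insertion is a single-base bulge on either strand and two
insertions may never be consumed back to back (the `b` flag in the matcher
state). An `N` in the *text* satisfies only a fully degenerate class, never
forms a valid pair, and is otherwise chargeable as a mismatch — assembly
gaps should not fabricate hits.

## Matching and search

Matchers are boolean dynamic programs returning, per distinct interval (or
interval pair), the lexicographically minimal distortion counts:
`(pattern prefix, text consumed, m, i)` for single strands and
`(column, strand lengths, m, r, i, b)` for helices. A bit-parallel
shift-and prefilter (per-budget-layer bit vectors with an epsilon closure
over wildcard skips) narrows candidate starts for large first-element
searches; it is deliberately loose and only ever over-reports, which the
test suite checks as an equivalence contract against the plain matcher.

The engine cuts each strand into windows of `W = max(20·L, 3000)` bases
overlapping by exactly `L` (the sum of per-occurrence maximal lengths), so
every occurrence lies wholly inside some window; duplicates from the
overlap are removed by the interval-tuple identity. Backtracking fixes one
element per step. The search domain of an unfixed occurrence is derived
from the nearest fixed occurrence on each side plus the min/max total
length of everything between (window edges minus minimal lengths when a
side is unfixed); helix strands additionally carry a joint gap constraint
`start3 − end5 ∈ [G_min, G_max]` accumulated over the map occurrences
separating the strands. These constraints are sound — they never exclude a
consistent completion — which makes the emitted set provably independent of
the search order; the property is enforced in tests against a brute-force
oracle that enumerates every tiling with no DP, no domains and no windows.

Occurrence identity is the full per-occurrence interval tuple; distinct
tuples over the same span are all reported (`--collapse-spans` keeps the
lexicographically smallest tuple per span instead). Reverse-strand hits
are found by scanning the reverse complement and reported on forward-axis
coordinates. Internally all coordinates are 0-based half-open; all printed
coordinates are 1-based inclusive.

## Ordering heuristics

`h1` is a lower bound on element information content: `2N − log2 X_U`
(single strand) or `4N − log2 X_U` (helix), N being the maximal strand
length including insertions. `X_U` upper-bounds the number of length-N
sequences (pairs of sequences for helices) containing a match, by counting
derivations:

* class columns — an exact DP over positions in which each position
  contributes its class size `C[i]` (pair count `P[j]` for helices) or, at
  the cost of one unit of mismatch budget (mismatch *or* mispair for
  helices, one shared DP), the complement `4 − C[i]` (`16 − P[j]`);
* a factor `4^k (k+1)` per block of k wildcards (`16^k (k+1)` for wildcard
  column blocks): the block matches 0..k bases and unused capacity frees
  tail bases;
* an insertion factor `Σ_j C(n+1, j)·u^j·t^(i−j)` with `u = 4, t = 4` for
  single strands and `u = 8 (strand × base), t = 16 (one free base per
  strand)` for helices. The unused-capacity term `t^(i−j)` matters: without
  it the "bound" is violated — e.g. the two-column Watson–Crick helix
  `AC:TG` with one bulge allowed has exactly 40 matching sequence pairs at
  N = 3, and dropping the term yields 25. With it the bound is provable
  (every matching sequence has at least one derivation) and monotone in
  every budget and class enlargement; the test suite verifies both against
  exhaustive enumeration on a grid of elements.

The mismatch relaxation makes `X_U` exact only at zero mismatch budget (a
mismatching position can coincide with sequences already counted), so the
bound property is asserted for `m = 0` elements, mirroring how the bound is
used.

`h2` sums the length flexibilities (max − min) of the occurrences between a
candidate element and the nearest already-placed occurrence on each side,
taking the minimum when both sides are anchored, the available side when
one is, and 0 for the very first element (a constant offset cannot change
the ranking at position 1). A helix is assessed per strand with its sibling
treated as placed, and the larger strand value is used.

Tuple score: `Σ_{i=1..k} 2^(k−i) (c1·h1(eᵢ) + c2·h2(e₁..eᵢ))` with
defaults k = 3, c1 = 3 (single) / 1 (paired), c2 = −0.2. Defaults live in
`HeuristicWeights` and are overridable. Tuples within 85 % of the best
score survive (when the best score is non-positive the threshold clamps to
the maximum, keeping its ties), at most 50, completed to full orders by
decreasing h1; ties anywhere break lexicographically for determinism.

## DDEO

While candidates survive, each window is searched with a uniformly drawn
survivor and the per-base CPU time recorded. After each new sample the
sampled candidate is Welch-tested one-sided (α = 0.01) against every other
survivor, eliminating whichever side is significantly slower; when both
members of a pair reach 75 samples undecided, the higher sample mean is
eliminated (mean ties break lexicographically — the choice is arbitrary
and documented rather than reconstructed). The surviving k-tuple is frozen
and the following k-tuple is trained over the remaining elements, their h2
now evaluated against the frozen prefix; fewer than k remaining elements
train as one shorter tuple. If input runs out first, the lowest-mean
survivor decides the rest. The timing clock is injectable, so tests drive
the controller with stubbed distributions and a seeded generator and get
bit-reproducible elimination; with real clocks the occurrence set is still
invariant — only the header's reported order can differ between runs.

## Synthetic data

The fixture generator emulates a desk-scale genome scan: an i.i.d.
background (uniform composition by default, GC fraction configurable) with
occurrences sampled from the descriptor — classes drawn uniformly from
their base sets, wildcards kept with probability 1/2, helix columns drawn
from the compatible allowed pairs, optional forced distortions — planted
without overlap at known coordinates. It does not model repeats,
low-complexity tracts, isochores or sequencing error, so passing the
recovery tests demonstrates correctness of the search, not real-genome
specificity: a descriptor loose enough will still drown in hits on real
low-complexity DNA exactly as it would in any descriptor-based scan. The
bundled ATP-aptamer-like and HDV-like descriptors are synthetic: they
reproduce published topologies (element counts, nesting, the double
pseudoknot) but their conserved sequences are invented for testing.

## Problem sizes and numerical choices

The acceptance checks run at sizes chosen to keep the whole suite in the
low minutes on one core: 200 seeded oracle-equivalence instances of
100–200 nt and 3–6 elements (the brute-force oracle is exponential and caps
at 300 nt / 6 elements by an explicit guard), 50 instances for
order/window invariance, 20 × 10-kb planted sequences (60 plants, both
strands), an upper-bound grid of single strands up to N = 8 (4^8
enumerations) and helices up to N = 4 (16^4 pairwise enumerations — joint
strand enumeration grows as 16^N, so helix grid sizes stay small), 100
stubbed DDEO runs and 100 Welch comparisons. `scripts/acceptance.py` uses
slightly smaller sweeps of the same generators.

Scores and bounds are computed in log2 space from exact big-integer counts,
so long elements cannot overflow. p-values come from the t-distribution CDF
(scipy) with Welch–Satterthwaite degrees of freedom; degenerate samples
(n < 2 or zero pooled variance) return the neutral 0.5 so that no
elimination can fire on them.

## Known limitations

* The matcher reports minimal distortion counts per interval but no scores;
  there is no energy model, no E-values, and no filtering beyond exact
  duplicate removal.
* The descriptor dialect is semantically equivalent to, but not
  byte-compatible with, other descriptor-based tools' formats.
* The brute-force oracle limits equivalence testing to small instances by
  design; correctness at genome scale rests on the window/overlap argument
  and the domain-soundness property, both tested, not on direct comparison.
* DDEO measures CPU time, so selection on real clocks is environment
  dependent (the result set never is).
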