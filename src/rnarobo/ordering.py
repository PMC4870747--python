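"""Search-order selection: heuristics plus data-driven elimination (DDEO).

Two per-element heuristics drive the choice of the first k elements of the
search order:

* ``h1`` -- a lower bound on the element's information content, measured in
  bits as background entropy minus post-match entropy: ``2N - log2(X_U)``
  for a single strand of maximal length N, ``4N - log2(X_U)`` for a helix
  strand pair, where ``X_U`` upper-bounds the number of sequences (or
  sequence pairs) of that length containing a match.  High h1 = specific
  element = good early filter (fail-first).
* ``h2`` -- the summed length flexibility of the map occurrences separating
  the element from the nearest already-placed element, a proxy for the size
  of its search domain.  Smaller is better.

A k-tuple e1..ek is scored ``sum_i 2^(k-i) (c1 h1(e_i) + c2 h2(e1..e_i))``
with exponentially decaying weights; c1 is larger for single strands
because they are cheaper to search.  High-scoring tuples are completed to
full orders by decreasing h1 and form the candidate set, which is then
whittled down empirically: each window is searched with a randomly drawn
surviving candidate, the normalized search time is recorded, and Welch's
one-sided t-test eliminates provably slower candidates (falling back to
the sample mean once both candidates have many samples).  The winner's
k-tuple is frozen and the procedure recurses on the next k-tuple.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .descriptor import Descriptor, HelixSpec, SingleStrandSpec, WILDCARD
from .engine import backtrack_window

__all__ = [
    "HeuristicWeights",
    "OrderCandidate",
    "h1_single",
    "h1_helix",
    "h1",
    "h2_flex",
    "score_tuple",
    "propose_candidates",
    "welch_one_sided",
    "heuristic_order",
    "DdeoController",
    "ddeo_controller",
]


@dataclass(frozen=True)
class HeuristicWeights:
    """Tunable constants of the ordering heuristics and the elimination test."""

    c1_single: float = 3.0
    c1_paired: float = 1.0
    c2: float = -0.2
    k: int = 3
    keep_fraction: float = 0.85
    max_candidates: int = 50
    alpha: float = 0.01
    max_samples: int = 75

    def __post_init__(self):
        if not (0 < self.keep_fraction <= 1):
            raise ValueError("keep_fraction must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# Information content (h1).


def _mismatch_count_log2(
    class_sizes: Sequence[int], complements: Sequence[int], budget: int
) -> float:
    """log2 of the number of position assignments with <= budget mismatches.

    DP over positions: each position contributes its class size, or its
    complement size at the cost of one mismatch.  Exact (big-int) count.
    """
    ways = [0] * (budget + 1)
    ways[0] = 1
    for c, comp in zip(class_sizes, complements):
        nxt = [0] * (budget + 1)
        for t in range(budget + 1):
            if not ways[t]:
                continue
            nxt[t] += ways[t] * c
            if t + 1 <= budget:
                nxt[t + 1] += ways[t] * comp
        ways = nxt
    total = sum(ways)
    return math.log2(total) if total else float("-inf")


def _insertion_factor_log2(
    n_tokens: int, budget: int, used: int, unused: int
) -> float:
    """log2 of sum_j C(n_tokens+1, j) * used^j * unused^(budget-j).

    Each of j realized insertions picks a junction and its content (``used``
    ways: 4 for a single strand, 8 = strand x base for a helix bulge); each
    unit of unrealized budget shortens the match and frees tail bases
    (``unused`` ways: 4, or 16 for the two helix strands).  Junctions are
    over-counted (the non-adjacency rule is ignored), so the sum upper
    bounds the true number of derivations.
    """
    total = sum(
        math.comb(n_tokens + 1, j) * used**j * unused ** (budget - j)
        for j in range(budget + 1)
    )
    return math.log2(total)


def h1_single(spec: SingleStrandSpec) -> float:
    """Information-content lower bound of a single-stranded element, in bits.

    ``2N - log2(X_U)`` with N the maximal occurrence length; X_U multiplies
    the exact count of class assignments with up to the mismatch budget,
    a factor ``4^k (k+1)`` per block of k wildcards, and the insertion
    placement bound.
    """
    n_max = spec.max_len
    sizes = [
        len(bs) for bs in spec.base_sets if bs is not None
    ]
    comps = [4 - c for c in sizes]
    log_xu = _mismatch_count_log2(sizes, comps, spec.max_mismatch)
    for k in spec.wildcard_blocks:
        log_xu += 2.0 * k + math.log2(k + 1)
    if spec.max_insert:
        log_xu += _insertion_factor_log2(
            len(spec.tokens), spec.max_insert, 4, 4
        )
    return 2.0 * n_max - log_xu


def h1_helix(spec: HelixSpec) -> float:
    """Information-content lower bound of a paired element, in bits.

    Background entropy is ``4N`` (two strands of maximal length N); X_U
    multiplies the count of column assignments where each column yields one
    of its P[j] allowed pairs -- or any of the 16 - P[j] others at the cost
    of one mispair or one mismatch -- a factor ``16^k (k+1)`` per block of
    k wildcard columns, and the bulge placement bound (junction x strand x
    base per bulge).
    """
    n_max = spec.max_len
    pcounts = [
        p
        for p, t in zip(spec.pair_counts, spec.tokens5)
        if t != WILDCARD
    ]
    comps = [16 - p for p in pcounts]
    log_xu = _mismatch_count_log2(
        pcounts, comps, spec.max_mispair + spec.max_mismatch
    )
    for k in spec.wildcard_blocks:
        log_xu += 4.0 * k + math.log2(k + 1)
    if spec.max_insert:
        log_xu += _insertion_factor_log2(
            spec.n_columns, spec.max_insert, 8, 16
        )
    return 4.0 * n_max - log_xu


def h1(spec: SingleStrandSpec | HelixSpec) -> float:
    return h1_helix(spec) if spec.is_helix else h1_single(spec)


def log2_upper_bound_count(spec: SingleStrandSpec | HelixSpec) -> float:
    """log2(X_U): the upper bound on the matching-sequence count behind h1."""
    if spec.is_helix:
        return 4.0 * spec.max_len - h1_helix(spec)
    return 2.0 * spec.max_len - h1_single(spec)


# ---------------------------------------------------------------------------
# Domain flexibility (h2).


def _occ_flex(descriptor: Descriptor, occ: str) -> int:
    spec = descriptor.occ_spec(occ)
    return spec.max_len - spec.min_len


def _side_flex(
    descriptor: Descriptor,
    fixed_occs: set[str],
    idx: int,
    direction: int,
) -> int | None:
    """Summed flexibility between map position idx and the nearest fixed
    occurrence in the given direction; None if that side has none fixed."""
    occs = descriptor.map.occurrences
    total = 0
    j = idx + direction
    while 0 <= j < len(occs):
        if occs[j] in fixed_occs:
            return total
        total += _occ_flex(descriptor, occs[j])
        j += direction
    return None


def _flex_for_occ(
    descriptor: Descriptor, fixed_occs: set[str], occ: str
) -> int:
    idx = descriptor.map.index_of(occ)
    left = _side_flex(descriptor, fixed_occs, idx, -1)
    right = _side_flex(descriptor, fixed_occs, idx, +1)
    if left is None and right is None:
        return 0
    if left is None:
        return right
    if right is None:
        return left
    return min(left, right)


def h2_flex(
    descriptor: Descriptor, fixed_prefix: Sequence[str], target: str
) -> int:
    """Positioning flexibility of ``target`` given already-placed elements.

    Sums the length flexibilities of the map occurrences separating the
    target from the nearest fixed occurrence on each side, and takes the
    minimum of the two sides (each an upper bound on the search-domain
    slack); one-sided when only one side has a fixed element, and 0 when
    nothing is placed yet.  For a helix the two strands are assessed
    individually -- each with the sibling strand counted as fixed -- and
    the larger value is returned.
    """
    if not fixed_prefix:
        return 0
    fixed_occs: set[str] = set()
    for tag in fixed_prefix:
        fixed_occs.add(tag)
        if descriptor.specs[tag].is_helix:
            fixed_occs.add(tag + "'")
    spec = descriptor.specs[target]
    if not spec.is_helix:
        return _flex_for_occ(descriptor, fixed_occs, target)
    f5 = _flex_for_occ(descriptor, fixed_occs | {target + "'"}, target)
    f3 = _flex_for_occ(descriptor, fixed_occs | {target}, target + "'")
    return max(f5, f3)


# ---------------------------------------------------------------------------
# Tuple scoring and candidate proposal.


def score_tuple(
    descriptor: Descriptor,
    tags: Sequence[str],
    weights: HeuristicWeights = HeuristicWeights(),
    fixed_prefix: Sequence[str] = (),
) -> float:
    """Weighted heuristic score of a candidate k-tuple.

    ``sum_i 2^(k-i) (c1 h1 + c2 h2)`` with h2 evaluated against
    ``fixed_prefix`` plus the tuple elements before position i.
    """
    k = weights.k
    score = 0.0
    prefix = list(fixed_prefix)
    for i, tag in enumerate(tags, start=1):
        spec = descriptor.specs[tag]
        c1 = weights.c1_paired if spec.is_helix else weights.c1_single
        score += 2.0 ** (k - i) * (
            c1 * h1(spec) + weights.c2 * h2_flex(descriptor, prefix, tag)
        )
        prefix.append(tag)
    return score


@dataclass
class OrderCandidate:
    """A full search order under empirical evaluation."""

    prefix: tuple[str, ...]
    full_order: tuple[str, ...]
    score: float = 0.0
    samples: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples)) if self.samples else math.inf

    @property
    def n(self) -> int:
        return len(self.samples)


def _completion(
    descriptor: Descriptor, prefix: Sequence[str]
) -> tuple[str, ...]:
    """Complete a prefix to a full order by decreasing information content."""
    rest = [t for t in descriptor.map.element_tags if t not in prefix]
    rest.sort(key=lambda t: (-h1(descriptor.specs[t]), t))
    return tuple(prefix) + tuple(rest)


def propose_candidates(
    descriptor: Descriptor,
    weights: HeuristicWeights = HeuristicWeights(),
    fixed_prefix: Sequence[str] = (),
) -> list[OrderCandidate]:
    """Score all ordered k-tuples and keep the competitive ones.

    Tuples scoring at least ``keep_fraction`` of the maximum survive, the
    top ``max_candidates`` of them by (score, lexicographic) order; each is
    completed to a full search order by decreasing h1.
    """
    tags = [t for t in descriptor.map.element_tags if t not in fixed_prefix]
    if not tags:
        raise ValueError("no elements left to order")
    k = min(weights.k, len(tags))
    scored = [
        (score_tuple(descriptor, tup, weights, fixed_prefix), tup)
        for tup in permutations(tags, k)
    ]
    best = max(s for s, _ in scored)
    threshold = min(best, weights.keep_fraction * best)
    kept = sorted(
        ((s, tup) for s, tup in scored if s >= threshold),
        key=lambda st: (-st[0], st[1]),
    )[: weights.max_candidates]
    return [
        OrderCandidate(
            tup,
            tuple(fixed_prefix) + _completion(descriptor, tuple(fixed_prefix) + tup)[len(fixed_prefix):],
            s,
        )
        for s, tup in kept
    ]


def heuristic_order(
    descriptor: Descriptor, weights: HeuristicWeights = HeuristicWeights()
) -> tuple[str, ...]:
    """Best-scoring k-tuple completed by information content (no timing)."""
    return propose_candidates(descriptor, weights)[0].full_order


# ---------------------------------------------------------------------------
# Welch's t-test.


def welch_one_sided(
    samples_x: Sequence[float], samples_y: Sequence[float]
) -> float:
    """One-sided Welch p-value for H1: E[X] < E[Y].

    Unequal-variance two-sample t statistic with Welch-Satterthwaite
    degrees of freedom.  Degenerate inputs (fewer than two samples on a
    side, or zero pooled variance) return the neutral 0.5.
    """
    x = np.asarray(samples_x, dtype=float)
    y = np.asarray(samples_y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return 0.5
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.5
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return float(stats.t.cdf(t, df))


# ---------------------------------------------------------------------------
# DDEO controller.


class DdeoController:
    """Online selection of the search order while windows are processed.

    Each window is searched with a random surviving candidate order and its
    CPU time per window base is recorded.  After every new sample the
    sampled candidate is tested pairwise against all survivors at level
    ``alpha``; once both members of a pair carry ``max_samples`` samples
    without a significant difference, the higher sample mean loses (ties
    broken lexicographically).  When one candidate is left its k-tuple is
    frozen and the next k-tuple is trained over the remaining elements;
    with every element frozen, remaining windows run with the final order.

    ``timing_source(order, text)``, when given, replaces the process-time
    measurement (the search itself still runs; only the clock is stubbed),
    making the controller deterministic for a seeded rng.
    """

    def __init__(
        self,
        descriptor: Descriptor,
        weights: HeuristicWeights,
        rng: np.random.Generator,
        timing_source: Callable[[tuple[str, ...], str], float] | None = None,
        candidates: list[OrderCandidate] | None = None,
    ):
        self.descriptor = descriptor
        self.weights = weights
        self.rng = rng
        self.timing_source = timing_source
        self.fixed_prefix: tuple[str, ...] = ()
        self.candidates: list[OrderCandidate] = (
            candidates
            if candidates is not None
            else propose_candidates(descriptor, weights)
        )
        self._settle_if_trivial()

    # -- state ------------------------------------------------------------

    @property
    def settled(self) -> bool:
        return len(self.fixed_prefix) == len(self.descriptor.map.element_tags)

    @property
    def final_order(self) -> tuple[str, ...]:
        if self.settled:
            return self.fixed_prefix
        best = min(self.candidates, key=lambda c: (c.mean, c.full_order))
        return best.full_order

    def _settle_if_trivial(self) -> None:
        while not self.settled and len(self.candidates) == 1:
            self._freeze_survivor()

    def _freeze_survivor(self) -> None:
        survivor = self.candidates[0]
        self.fixed_prefix = self.fixed_prefix + survivor.prefix
        remaining = [
            t
            for t in self.descriptor.map.element_tags
            if t not in self.fixed_prefix
        ]
        if not remaining:
            return
        self.candidates = propose_candidates(
            self.descriptor, self.weights, self.fixed_prefix
        )

    # -- sampling ---------------------------------------------------------

    def run_window(self, text: str) -> set[tuple[tuple[int, int], ...]]:
        """Search one window, recording a timing sample while unsettled."""
        if self.settled:
            return backtrack_window(text, self.descriptor, self.fixed_prefix)
        cand = self.candidates[int(self.rng.integers(len(self.candidates)))]
        t0 = time.process_time_ns()
        result = backtrack_window(text, self.descriptor, cand.full_order)
        elapsed = time.process_time_ns() - t0
        if self.timing_source is not None:
            sample = float(self.timing_source(cand.full_order, text))
        else:
            sample = elapsed / max(1, len(text))
        self.record(cand, sample)
        return result

    def record(self, cand: OrderCandidate, sample: float) -> None:
        cand.samples.append(sample)
        self._eliminate_against(cand)
        self._settle_if_trivial()

    def _eliminate_against(self, cand: OrderCandidate) -> None:
        alpha = self.weights.alpha
        losers: set[int] = set()
        for j, other in enumerate(self.candidates):
            if other is cand or j in losers:
                continue
            if welch_one_sided(cand.samples, other.samples) < alpha:
                losers.add(j)
                continue
            if welch_one_sided(other.samples, cand.samples) < alpha:
                losers.add(self.candidates.index(cand))
                break
            if (
                cand.n >= self.weights.max_samples
                and other.n >= self.weights.max_samples
            ):
                if (cand.mean, cand.full_order) > (other.mean, other.full_order):
                    losers.add(self.candidates.index(cand))
                    break
                losers.add(j)
        if losers:
            self.candidates = [
                c for j, c in enumerate(self.candidates) if j not in losers
            ]


def ddeo_controller(
    descriptor: Descriptor,
    windows: Iterable[str],
    weights: HeuristicWeights,
    rng: np.random.Generator,
    timing_source: Callable[[tuple[str, ...], str], float] | None = None,
) -> tuple[tuple[str, ...], set[tuple[tuple[int, int], ...]]]:
    """Drive a controller over a window stream.

    Returns the final full search order and the union of window-relative
    occurrence tuples found along the way (identical to any fixed-order
    run on the same windows).  If the stream is exhausted before the order
    settles, the lowest-mean surviving candidate decides the remainder.
    """
    ctl = DdeoController(descriptor, weights, rng, timing_source)
    found: set[tuple[tuple[int, int], ...]] = set()
    for text in windows:
        found |= ctl.run_window(text)
    return ctl.final_order, found
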