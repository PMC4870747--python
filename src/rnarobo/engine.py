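"""Windowed backtracking search over whole sequences.

The sequence is cut into windows of ``max(20 L, 3000)`` bases (L = maximum
motif occurrence length) overlapping by L, so every occurrence is wholly
inside at least one window.  Within a window, elements are matched one by
one in a given search order; each new element is restricted to the *search
domain* implied by the closest already-fixed occurrences on either side and
the length flexibility of the occurrences in between.  The search order
affects speed only: the emitted occurrence set is order-invariant.

An occurrence is a contiguous 5'->3' tiling of a substring by the map
occurrences (helix strands placed jointly); its identity is the full
per-occurrence interval tuple.  Coordinates are 0-based half-open
internally and converted to 1-based inclusive only on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .descriptor import Descriptor
from .matcher import SearchDomain, match_helix, match_single

__all__ = [
    "Window",
    "Occurrence",
    "make_windows",
    "compute_search_domain",
    "backtrack_window",
    "search",
    "SearchOptions",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Window:
    """A window of the scanned strand; coordinates on that strand's axis."""

    start: int
    end: int
    text: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Occurrence:
    """A complete motif occurrence on one strand of one sequence.

    ``intervals`` holds one 0-based half-open interval per map occurrence,
    on the axis of the scanned strand for '+' hits and converted to the
    forward axis for '-' hits (start <= end always; the tuple order still
    follows the motif map on the scanned strand).
    """

    seq_id: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(s for s, _ in self.intervals),
            max(e for _, e in self.intervals),
        )


def make_windows(
    seq_len: int, L: int, window_size: int | None = None
) -> list[tuple[int, int]]:
    """0-based half-open window intervals covering the sequence.

    Windows have size ``max(20 L, 3000)`` (or ``window_size`` if given) and
    consecutive windows overlap by exactly L, so every substring of length
    <= L lies wholly inside at least one window.
    """
    if seq_len < 1 or L < 1:
        raise ValueError("seq_len and L must be positive")
    W = window_size if window_size is not None else max(20 * L, 3000)
    W = max(W, L + 1)
    if seq_len <= W:
        return [(0, seq_len)]
    out = []
    start = 0
    while True:
        end = start + W
        if end >= seq_len:
            out.append((start, seq_len))
            return out
        out.append((start, end))
        start = end - L


def _fixed_neighbors(
    occs: tuple[str, ...],
    idx: int,
    fixed: dict[str, tuple[int, int]],
    bounds: list[tuple[int, int]],
) -> tuple[int | None, int, int, int | None, int, int]:
    """Nearest fixed occurrence on each side of map position ``idx``.

    Returns (left fixed end, min/max total length between it and the
    target, right fixed start, min/max total length on that side); the
    fixed position is None when the whole side is unfixed, in which case
    the min/max cover every occurrence on that side.
    """
    lmin = lmax = 0
    left_end = None
    for j in range(idx - 1, -1, -1):
        if occs[j] in fixed:
            left_end = fixed[occs[j]][1]
            break
        lmin += bounds[j][0]
        lmax += bounds[j][1]
    rmin = rmax = 0
    right_start = None
    for j in range(idx + 1, len(occs)):
        if occs[j] in fixed:
            right_start = fixed[occs[j]][0]
            break
        rmin += bounds[j][0]
        rmax += bounds[j][1]
    return left_end, lmin, lmax, right_start, rmin, rmax


def _domain_for_occ(
    descriptor: Descriptor,
    fixed: dict[str, tuple[int, int]],
    occ: str,
    text_len: int,
    bounds: list[tuple[int, int]],
) -> SearchDomain:
    occs = descriptor.map.occurrences
    idx = occs.index(occ)
    min_len = bounds[idx][0]
    left_end, lmin, lmax, right_start, rmin, rmax = _fixed_neighbors(
        occs, idx, fixed, bounds
    )
    if left_end is not None:
        s_lo, s_hi = left_end + lmin, left_end + lmax
    else:
        s_lo, s_hi = lmin, None
    if right_start is not None:
        e_lo, e_hi = right_start - rmax, right_start - rmin
    else:
        e_lo, e_hi = None, text_len - rmin
    if s_hi is None:
        s_hi = e_hi - min_len
    if e_lo is None:
        e_lo = s_lo + min_len
    s_lo, e_lo = max(0, s_lo), max(0, e_lo)
    s_hi, e_hi = min(text_len, s_hi), min(text_len, e_hi)
    return SearchDomain((s_lo, s_hi), (e_lo, e_hi))


def compute_search_domain(
    descriptor: Descriptor,
    fixed: dict[str, tuple[int, int]],
    target: str,
    text_len: int,
) -> SearchDomain | tuple[SearchDomain, SearchDomain, tuple[int, int]]:
    """Search domain(s) for an unfixed element given fixed occurrences.

    ``fixed`` maps map-occurrence tags (primed for 3' helix strands) to
    0-based half-open intervals.  For a single-strand target returns one
    :class:`SearchDomain`; for a helix target returns the two strand
    domains plus the joint (min, max) bound on the gap between them (the
    total length of the map occurrences separating the strands, fixed ones
    counted exactly).  The constraints are sound: no completion of the
    motif consistent with ``fixed`` is excluded.
    """
    occs = descriptor.map.occurrences
    bounds = [descriptor.occ_bounds(o) for o in occs]
    spec = descriptor.specs[target.rstrip("'")]
    if not spec.is_helix:
        return _domain_for_occ(descriptor, fixed, target, text_len, bounds)
    tag = target.rstrip("'")
    dom5 = _domain_for_occ(descriptor, fixed, tag, text_len, bounds)
    dom3 = _domain_for_occ(descriptor, fixed, tag + "'", text_len, bounds)
    i5, i3 = occs.index(tag), occs.index(tag + "'")
    gmin = gmax = 0
    for j in range(i5 + 1, i3):
        if occs[j] in fixed:
            a, b = fixed[occs[j]]
            gmin += b - a
            gmax += b - a
        else:
            gmin += bounds[j][0]
            gmax += bounds[j][1]
    return dom5, dom3, (gmin, gmax)


def _contiguous(
    occs: tuple[str, ...], fixed: dict[str, tuple[int, int]]
) -> bool:
    prev_end = None
    for occ in occs:
        s, e = fixed[occ]
        if prev_end is not None and s != prev_end:
            return False
        prev_end = e
    return True


def backtrack_window(
    text: str,
    descriptor: Descriptor,
    order: list[str] | tuple[str, ...],
) -> set[tuple[tuple[int, int], ...]]:
    """All motif occurrences wholly inside one window of text.

    ``order`` lists each element tag once (helices unprimed); both strands
    of a helix are fixed in one step.  Returns the set of per-map-occurrence
    interval tuples (0-based, window-relative).  The result does not depend
    on ``order``.
    """
    if sorted(order) != sorted(descriptor.map.element_tags):
        raise ValueError("order must be a permutation of the element tags")
    occs = descriptor.map.occurrences
    n = len(text)
    results: set[tuple[tuple[int, int], ...]] = set()
    use_prefilter_depth0 = n > 400

    def rec(depth: int, fixed: dict[str, tuple[int, int]]):
        if depth == len(order):
            if _contiguous(occs, fixed):
                results.add(tuple(fixed[o] for o in occs))
            return
        tag = order[depth]
        spec = descriptor.specs[tag]
        if spec.is_helix:
            dom5, dom3, gap = compute_search_domain(descriptor, fixed, tag, n)
            for hm in match_helix(spec, text, dom5, dom3, gap):
                fixed[tag] = (hm.start5, hm.end5)
                fixed[tag + "'"] = (hm.start3, hm.end3)
                rec(depth + 1, fixed)
                del fixed[tag], fixed[tag + "'"]
        else:
            dom = compute_search_domain(descriptor, fixed, tag, n)
            pf = depth == 0 and use_prefilter_depth0
            for sm in match_single(spec, text, dom, prefilter=pf):
                fixed[tag] = (sm.start, sm.end)
                rec(depth + 1, fixed)
                del fixed[tag]

    rec(0, {})
    return results


@dataclass
class SearchOptions:
    """Options for :func:`search`."""

    strand: str = "+"  # '+', '-' or 'both'
    ordering: str = "heuristic"  # 'user' | 'heuristic' | 'ddeo'
    order: tuple[str, ...] | None = None  # explicit order (implies 'user')
    seed: int = 0
    window_size: int | None = None
    collapse_spans: bool = False


def _resolve_order(
    descriptor: Descriptor, options: SearchOptions
) -> tuple[str, ...]:
    from . import ordering as _ord

    if options.order is not None:
        return tuple(options.order)
    if options.ordering == "user":
        if descriptor.user_order is None:
            raise ValueError("descriptor has no search order line")
        return descriptor.user_order
    return _ord.heuristic_order(descriptor)


def search(
    sequences: Iterable[tuple[str, str]],
    descriptor: Descriptor,
    options: SearchOptions | None = None,
) -> Iterator[Occurrence]:
    """Scan sequences for motif occurrences.

    ``sequences`` yields (id, sequence) pairs of uppercase A/C/G/T/N text.
    Hits on the reverse strand are found by scanning the reverse complement
    and reported with strand '-' on forward-axis coordinates.  Within each
    sequence the output is sorted by (strand, span, interval tuple) and
    exact duplicates arising from window overlap are emitted once.
    """
    options = options or SearchOptions()
    if options.strand not in {"+", "-", "both"}:
        raise ValueError(f"bad strand selection {options.strand!r}")
    strands = ["+", "-"] if options.strand == "both" else [options.strand]
    L = descriptor.L
    if options.window_size is not None and options.window_size < L:
        raise ValueError("window override smaller than the motif length L")

    ddeo_ctl = None
    if options.ordering == "ddeo":
        from .ordering import DdeoController, HeuristicWeights
        import numpy as np

        ddeo_ctl = DdeoController(
            descriptor,
            HeuristicWeights(),
            np.random.default_rng(options.seed),
        )
    fixed_order = None if ddeo_ctl is not None else _resolve_order(
        descriptor, options
    )

    for seq_id, seq in sequences:
        if not seq:
            continue
        per_seq: set[Occurrence] = set()
        for strand in strands:
            text = seq if strand == "+" else reverse_complement(seq)
            seen: set[tuple[tuple[int, int], ...]] = set()
            for ws, we in make_windows(len(text), L, options.window_size):
                wtext = text[ws:we]
                if ddeo_ctl is not None:
                    tuples = ddeo_ctl.run_window(wtext)
                else:
                    tuples = backtrack_window(wtext, descriptor, fixed_order)
                for tup in tuples:
                    seen.add(tuple((s + ws, e + ws) for s, e in tup))
            for tup in seen:
                if strand == "-":
                    n = len(seq)
                    tup = tuple((n - e, n - s) for s, e in tup)
                per_seq.add(Occurrence(seq_id, strand, tup))
        if options.collapse_spans:
            by_span: dict[tuple[str, tuple[int, int]], Occurrence] = {}
            for occ in per_seq:
                key = (occ.strand, occ.span)
                cur = by_span.get(key)
                if cur is None or occ.intervals < cur.intervals:
                    by_span[key] = occ
            per_seq = set(by_span.values())
        for occ in sorted(
            per_seq, key=lambda o: (o.span, o.strand, o.intervals)
        ):
            yield occ
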