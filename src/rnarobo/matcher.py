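"""Element matchers: find all placements of one element in a search domain.

Single-stranded elements are matched by a dynamic program over states
(pattern prefix, text consumed, mismatches, insertions); paired elements by
a program over (column, strand lengths, mismatches, mispairs, insertions,
last-step-was-insertion).  Both report every distinct interval admitting an
alignment within the distortion budgets, each with the lexicographically
minimal distortion counts over its alignments.

Coordinates are 0-based half-open throughout this module.  An ``N`` in the
text satisfies only a fully degenerate pattern class and never forms a
valid base pair; any other violation of a class is a mismatch, of the pair
set a mispair, both chargeable to their budgets.  Insertions are internal:
they consume a text base at a junction between two pattern tokens (for
helices: a single-base bulge on either strand between two columns, never
immediately after another bulge).
"""

from __future__ import annotations

from dataclasses import dataclass

from .descriptor import IUPAC_BASES, HelixSpec, SingleStrandSpec

__all__ = [
    "SearchDomain",
    "SingleMatch",
    "HelixMatch",
    "match_single",
    "match_helix",
    "prefilter_positions",
]

_FULL = IUPAC_BASES["N"]


@dataclass(frozen=True)
class SearchDomain:
    """Positional constraints on one element strand.

    ``start`` is the inclusive range of allowed match start positions,
    ``end`` the inclusive range of allowed (exclusive) end positions, and
    ``cover``, if given, a half-open interval the match must contain.  An
    interval with lo > hi is empty and admits no matches.
    """

    start: tuple[int, int]
    end: tuple[int, int]
    cover: tuple[int, int] | None = None

    @classmethod
    def full(cls, text_len: int) -> "SearchDomain":
        return cls((0, text_len), (0, text_len))

    @property
    def is_empty(self) -> bool:
        return self.start[0] > self.start[1] or self.end[0] > self.end[1]

    def admits(self, start: int, end: int) -> bool:
        if not (self.start[0] <= start <= self.start[1]):
            return False
        if not (self.end[0] <= end <= self.end[1]):
            return False
        if self.cover is not None and self.cover[0] < self.cover[1]:
            if not (start <= self.cover[0] and self.cover[1] <= end):
                return False
        return True


@dataclass(frozen=True, order=True)
class SingleMatch:
    start: int
    end: int
    mismatches_used: int = 0
    insertions_used: int = 0


@dataclass(frozen=True, order=True)
class HelixMatch:
    start5: int
    end5: int
    start3: int
    end3: int
    mismatches_used: int = 0
    mispairs_used: int = 0
    insertions_used: int = 0


def _accepts(base_set: frozenset[str] | None, ch: str) -> bool:
    """Class membership; text 'N' satisfies only the full class / a wildcard."""
    if base_set is None:
        return True
    if ch == "N":
        return base_set == _FULL
    return ch in base_set


def match_single(
    spec: SingleStrandSpec,
    text: str,
    domain: SearchDomain,
    prefilter: bool = False,
) -> list[SingleMatch]:
    """All matches of a single-stranded element inside ``domain``.

    Returns one :class:`SingleMatch` per distinct interval, carrying the
    minimal (mismatches, insertions) pair over its alignments, sorted by
    position.  With ``prefilter=True`` a bit-parallel shift-and pass first
    narrows the candidate starts (the result is identical by contract).
    """
    if domain.is_empty:
        return []
    n = len(text)
    sets = spec.base_sets
    plen = len(sets)
    m_max, i_max = spec.max_mismatch, spec.max_insert
    max_t = spec.max_len
    lo = max(0, domain.start[0])
    hi = min(n, domain.start[1])
    if lo > hi:
        return []
    if prefilter:
        starts: set[int] = set()
        for e in prefilter_positions(spec, text, domain):
            starts.update(
                range(max(lo, e - spec.max_len), min(hi, e - spec.min_len) + 1)
            )
        start_iter: list[int] | range = sorted(starts)
    else:
        start_iter = range(lo, hi + 1)

    out: list[SingleMatch] = []
    for s in start_iter:
        # layer = set of (text consumed, mismatches, insertions) states
        layer: set[tuple[int, int, int]] = {(0, 0, 0)}
        for p in range(plen):
            if p >= 1 and i_max:
                # internal junction: chain of insertions, each one text base
                frontier = layer
                while frontier:
                    added = set()
                    for t, mm, ins in frontier:
                        if ins < i_max and s + t < n and t < max_t:
                            st = (t + 1, mm, ins + 1)
                            if st not in layer:
                                added.add(st)
                    layer = layer | added
                    frontier = added
            nxt: set[tuple[int, int, int]] = set()
            bs = sets[p]
            for t, mm, ins in layer:
                pos = s + t
                if bs is None:
                    nxt.add((t, mm, ins))  # wildcard matches the empty string
                    if pos < n and t < max_t:
                        nxt.add((t + 1, mm, ins))
                elif pos < n and t < max_t:
                    if _accepts(bs, text[pos]):
                        nxt.add((t + 1, mm, ins))
                    elif mm < m_max:
                        nxt.add((t + 1, mm + 1, ins))
            layer = nxt
            if not layer:
                break
        finals: dict[int, tuple[int, int]] = {}
        for t, mm, ins in layer:
            cur = finals.get(t)
            if cur is None or (mm, ins) < cur:
                finals[t] = (mm, ins)
        for t, (mm, ins) in finals.items():
            if domain.admits(s, s + t):
                out.append(SingleMatch(s, s + t, mm, ins))
    out.sort()
    return out


def _pair_ok(pairs: frozenset[str], x: str, y: str) -> bool:
    if x == "N" or y == "N":
        return False
    return x + y in pairs


def match_helix(
    spec: HelixSpec,
    text: str,
    domain5: SearchDomain,
    domain3: SearchDomain,
    gap: tuple[int, int] | None = None,
) -> list[HelixMatch]:
    """All joint placements of the two strands of a helix.

    The helix is zipped from the outside in: column *j* consumes one base
    rightwards from the 5'-strand start and one base leftwards from the
    3'-strand end.  ``gap``, when given, constrains ``start3 - end5`` (the
    total length of map occurrences between the two strands) to a closed
    interval, which also bounds the anchor pairs enumerated.  Returns one
    :class:`HelixMatch` per distinct interval pair, with the minimal
    (mismatches, mispairs, insertions) triple, sorted by position.
    """
    if domain5.is_empty or domain3.is_empty:
        return []
    n = len(text)
    sets5, sets3 = spec.base_sets5, spec.base_sets3
    pairs = spec.allowed_pairs
    ncol = spec.n_columns
    m_max, r_max, i_max = spec.max_mismatch, spec.max_mispair, spec.max_insert
    min_l, max_l = spec.min_len, spec.max_len

    a_lo = max(0, domain5.start[0])
    a_hi = min(n, domain5.start[1])
    d_lo = max(0, domain3.end[0])
    d_hi = min(n, domain3.end[1])
    if a_lo > a_hi or d_lo > d_hi:
        return []

    best: dict[tuple[int, int, int, int], tuple[int, int, int]] = {}
    for a in range(a_lo, a_hi + 1):
        if gap is not None:
            dmin = a + 2 * min_l + max(0, gap[0])
            dmax = a + 2 * max_l + gap[1]
        else:
            dmin, dmax = a + 2 * min_l, n
        for d in range(max(d_lo, dmin), min(d_hi, dmax) + 1):
            # states: (columns done, len5, len3, mm, mp, ins, bulge flag b)
            seen: set[tuple[int, int, int, int, int, int, bool]] = set()
            stack = [(0, 0, 0, 0, 0, 0, False)]
            while stack:
                state = stack.pop()
                if state in seen:
                    continue
                seen.add(state)
                col, l5, l3, mm, mp, ins, b = state
                if col == ncol:
                    e5, s3 = a + l5, d - l3
                    if e5 > s3 or s3 < 0 or e5 > n:
                        continue
                    if gap is not None and not (gap[0] <= s3 - e5 <= gap[1]):
                        continue
                    if not (domain5.admits(a, e5) and domain3.admits(s3, d)):
                        continue
                    key = (a, e5, s3, d)
                    cur = best.get(key)
                    if cur is None or (mm, mp, ins) < cur:
                        best[key] = (mm, mp, ins)
                    continue
                x_pos, y_pos = a + l5, d - l3 - 1
                if sets5[col] is None:
                    # optional column (wildcard on both strands): skip it
                    stack.append((col + 1, l5, l3, mm, mp, ins, b))
                if 0 <= x_pos < y_pos < n:
                    x, y = text[x_pos], text[y_pos]
                    nmm = mm
                    if not _accepts(sets5[col], x):
                        nmm += 1
                    if not _accepts(sets3[col], y):
                        nmm += 1
                    nmp = mp + (0 if _pair_ok(pairs, x, y) else 1)
                    if nmm <= m_max and nmp <= r_max:
                        stack.append((col + 1, l5 + 1, l3 + 1, nmm, nmp, ins, False))
                # single-base bulge on either strand between two columns
                if (ins < i_max and not b and 1 <= col <= ncol - 1
                        and 0 <= x_pos <= y_pos < n):
                    if l5 < max_l:
                        stack.append((col, l5 + 1, l3, mm, mp, ins + 1, True))
                    if l3 < max_l:
                        stack.append((col, l5, l3 + 1, mm, mp, ins + 1, True))
    out = [
        HelixMatch(a, e5, s3, d, mm, mp, ins)
        for (a, e5, s3, d), (mm, mp, ins) in best.items()
    ]
    out.sort()
    return out


def prefilter_positions(
    spec: SingleStrandSpec, text: str, domain: SearchDomain
) -> set[int]:
    """Bit-parallel shift-and pass returning a superset of match end positions.

    One bit vector per (mismatch, insertion) budget layer tracks the set of
    pattern prefixes alignable to a suffix of the scanned text; wildcard
    tokens add epsilon (skip) transitions closed after every step.  The
    pass is deliberately loose -- mismatches are chargeable at any token
    and insertions anywhere -- so it can only over-report, never miss an
    end position of a true match (the equivalence contract tested against
    :func:`match_single`).
    """
    if domain.is_empty:
        return set()
    sets = spec.base_sets
    plen = len(sets)
    m_max, i_max = spec.max_mismatch, spec.max_insert
    accept = 1 << plen
    full = (1 << (plen + 1)) - 1
    wild = 0
    A = {c: 0 for c in "ACGTN"}
    for j, bs in enumerate(sets):
        bit = 1 << j
        if bs is None:
            wild |= bit
            for c in A:
                A[c] |= bit
        else:
            for c in "ACGT":
                if c in bs:
                    A[c] |= bit
            if bs == _FULL:
                A["N"] |= bit

    def close(r: int) -> int:
        while True:
            add = ((r & wild) << 1) & full & ~r
            if not add:
                return r
            r |= add

    seed = close(1)
    R = [[seed] * (i_max + 1) for _ in range(m_max + 1)]
    ends: set[int] = set()
    e_lo, e_hi = domain.end
    if e_lo <= 0 <= e_hi and seed & accept:
        ends.add(0)
    for pos in range(min(len(text), e_hi)):
        cm = A.get(text[pos], A["N"])
        new = [[0] * (i_max + 1) for _ in range(m_max + 1)]
        for mm in range(m_max + 1):
            for ins in range(i_max + 1):
                r = ((R[mm][ins] & cm) << 1) & full
                if mm:
                    r |= (R[mm - 1][ins] << 1) & full
                if ins:
                    r |= R[mm][ins - 1]  # consume text, hold pattern position
                new[mm][ins] = close(r | 1)
        R = new
        e = pos + 1
        if e_lo <= e <= e_hi and any(
            r & accept for row in R for r in row
        ):
            ends.add(e)
    return ends
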