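"""Synthetic data with ground truth, toy descriptors, and a brute-force oracle.

The oracle (:func:`brute_force_search`) enumerates every assignment of
contiguous intervals to the motif map and tests each element placement by
exhaustive alignment enumeration.  It shares no code with the dynamic
programming matchers or the windowed engine, and is deliberately order-free
and window-free: any disagreement with the engine on an instance small
enough for the oracle is an engine defect.

The planted-sequence generator emulates a genome scan at desk scale:
an i.i.d. background (uniform base composition by default) with motif
occurrences sampled from the descriptor and placed without overlap at
known coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptor import (
    IUPAC_BASES,
    WILDCARD,
    Descriptor,
    HelixSpec,
    MotifMap,
    SingleStrandSpec,
    parse_descriptor,
)

__all__ = [
    "PlantedTruth",
    "sample_occurrence",
    "generate_planted_sequence",
    "brute_force_search",
    "random_descriptor",
    "atp_aptamer_like",
    "hdv_like",
]

_BASES = "ACGT"

# ---------------------------------------------------------------------------
# Bundled toy descriptors.
#
# Both are SYNTHETIC: they reproduce the published topologies (element
# counts and pseudoknot structure) of well-studied motifs, but their
# conserved sequences are invented for testing, not transcribed from any
# real aptamer or ribozyme.

#: ATP-aptamer-like motif: two nested helices, a conserved loop and a
#: variable-length joining strand (synthetic sequence content).
ATP_APTAMER_LIKE = """\
name: atp-aptamer-like-synthetic
h1 s1 h2 s2 h2' s3 h1'
h1 0:0:0 NNNNNN:NNNNNN
s1 0:0 ACCTGGGAG
h2 0:0:0 NNNN:NNNN
s2 0:0 N****
s3 0:0 TGCGGAAGGT
"""

#: HDV-like motif: four helices organised in a double pseudoknot (h1/h2
#: and h1/h3 interleave), with one strongly conserved single strand
#: (synthetic sequence content).
HDV_LIKE = """\
name: hdv-like-synthetic
h1 s1 h2 s2 h3 h1' s3 h4 s4 h4' h3' s5 h2'
h1 0:0:0 NNNNN:NNNNN
h2 0:0:0 NNNN:NNNN
h3 0:0:0 NNN:NNN
h4 0:0:0 NNNN:NNNN
s1 0:0 G**
s2 0:0 C*
s3 0:0 CTTCGGATG
s4 0:0 N***
s5 0:0 CA
"""


def atp_aptamer_like() -> Descriptor:
    """Parsed bundled ATP-aptamer-like toy descriptor (synthetic content)."""
    return parse_descriptor(ATP_APTAMER_LIKE)


def hdv_like() -> Descriptor:
    """Parsed bundled HDV-like double-pseudoknot toy descriptor (synthetic)."""
    return parse_descriptor(HDV_LIKE)


# ---------------------------------------------------------------------------
# Brute-force alignment enumerators (independent of the DP matchers).


def _ss_distortion_set(
    spec: SingleStrandSpec, chunk: str
) -> set[tuple[int, int]]:
    """All (mismatches, insertions) over full alignments of pattern to chunk."""
    sets = spec.base_sets
    plen = len(sets)
    m_max, i_max = spec.max_mismatch, spec.max_insert
    full = IUPAC_BASES["N"]
    out: set[tuple[int, int]] = set()

    def rec(p: int, t: int, mm: int, ins: int) -> None:
        if p == plen:
            if t == len(chunk):
                out.add((mm, ins))
            return
        bs = sets[p]
        if bs is None:
            rec(p + 1, t, mm, ins)  # wildcard matches the empty string
            if t < len(chunk):
                rec(p + 1, t + 1, mm, ins)
        elif t < len(chunk):
            ch = chunk[t]
            ok = (ch in bs) if ch != "N" else (bs == full)
            if ok:
                rec(p + 1, t + 1, mm, ins)
            elif mm < m_max:
                rec(p + 1, t + 1, mm + 1, ins)
        # internal insertion between token p-1 and token p
        if 1 <= p <= plen - 1 and ins < i_max and t < len(chunk):
            rec(p, t + 1, mm, ins + 1)

    rec(0, 0, 0, 0)
    return out


def _hx_distortion_set(
    spec: HelixSpec, chunk5: str, chunk3: str
) -> set[tuple[int, int, int]]:
    """All (mismatches, mispairs, insertions) over joint strand alignments."""
    sets5, sets3 = spec.base_sets5, spec.base_sets3
    pairs = spec.allowed_pairs
    ncol = spec.n_columns
    m_max, r_max, i_max = spec.max_mismatch, spec.max_mispair, spec.max_insert
    full = IUPAC_BASES["N"]
    n5, n3 = len(chunk5), len(chunk3)
    out: set[tuple[int, int, int]] = set()

    def member(bs: frozenset[str] | None, ch: str) -> bool:
        if bs is None:
            return True
        return (ch in bs) if ch != "N" else (bs == full)

    def rec(col: int, i5: int, i3: int, mm: int, mp: int, ins: int, b: bool):
        if mm > m_max or mp > r_max or ins > i_max:
            return
        if col == ncol:
            if i5 == n5 and i3 == n3:
                out.add((mm, mp, ins))
            return
        if sets5[col] is None:
            rec(col + 1, i5, i3, mm, mp, ins, b)
        if i5 < n5 and i3 < n3:
            x = chunk5[i5]
            y = chunk3[n3 - 1 - i3]
            nmm = mm + (0 if member(sets5[col], x) else 1)
            nmm += 0 if member(sets3[col], y) else 1
            paired = x != "N" and y != "N" and x + y in pairs
            rec(col + 1, i5 + 1, i3 + 1, nmm, mp + (0 if paired else 1), ins, False)
        if not b and 1 <= col <= ncol - 1 and ins < i_max:
            if i5 < n5:
                rec(col, i5 + 1, i3, mm, mp, ins + 1, True)
            if i3 < n3:
                rec(col, i5, i3 + 1, mm, mp, ins + 1, True)

    rec(0, 0, 0, 0, 0, 0, False)
    return out


def single_chunk_ok(spec: SingleStrandSpec, chunk: str) -> bool:
    """True if the chunk is a valid occurrence of the element within budgets."""
    return any(
        mm <= spec.max_mismatch and ins <= spec.max_insert
        for mm, ins in _ss_distortion_set(spec, chunk)
    )


def helix_chunks_ok(spec: HelixSpec, chunk5: str, chunk3: str) -> bool:
    return bool(_hx_distortion_set(spec, chunk5, chunk3))


# ---------------------------------------------------------------------------
# Full-search oracle.


def brute_force_search(
    descriptor: Descriptor, text: str
) -> set[tuple[tuple[int, int], ...]]:
    """Exhaustive motif search; the reference for engine equivalence tests.

    Enumerates every 5'->3' assignment of contiguous (possibly empty)
    intervals to the map occurrences and keeps those where every element
    placement admits an alignment within its budgets.  Returns the set of
    per-occurrence interval tuples (0-based half-open).  Guarded against
    accidental blow-up: refuses texts over 300 nt or maps over 6 elements.
    """
    if len(text) > 300:
        raise ValueError("oracle guard: text longer than 300 nt")
    if len(descriptor.map.element_tags) > 6:
        raise ValueError("oracle guard: more than 6 elements")
    occs = descriptor.map.occurrences
    bounds = [descriptor.occ_bounds(o) for o in occs]
    tail_min = [0] * (len(occs) + 1)
    for i in range(len(occs) - 1, -1, -1):
        tail_min[i] = tail_min[i + 1] + bounds[i][0]
    n = len(text)
    results: set[tuple[tuple[int, int], ...]] = set()

    def rec(idx: int, pos: int, intervals: list[tuple[int, int]]):
        if idx == len(occs):
            results.add(tuple(intervals))
            return
        occ = occs[idx]
        spec = descriptor.occ_spec(occ)
        omin, omax = bounds[idx]
        for ln in range(omin, omax + 1):
            end = pos + ln
            if end + tail_min[idx + 1] > n:
                break
            chunk = text[pos:end]
            if spec.is_helix:
                if occ.endswith("'"):
                    k5 = next(
                        iv for o, iv in zip(occs, intervals) if o == occ[:-1]
                    )
                    if not helix_chunks_ok(spec, text[k5[0]:k5[1]], chunk):
                        continue
                # 5' strand: defer the joint check to the primed occurrence
            else:
                if not single_chunk_ok(spec, chunk):
                    continue
            intervals.append((pos, end))
            rec(idx + 1, end, intervals)
            intervals.pop()

    for s0 in range(n + 1):
        if s0 + tail_min[0] > n:
            break
        rec(0, s0, [])
    return results


# ---------------------------------------------------------------------------
# Random descriptors (for property tests and seeded equivalence sweeps).


def random_descriptor(
    rng: np.random.Generator,
    n_elements: tuple[int, int] = (3, 6),
    max_strand_len: int = 6,
    max_budget: int = 2,
    force_pseudoknot: bool = False,
) -> Descriptor:
    """Sample a small random descriptor.

    Helices are interleaved at random, so pseudoknotted topologies arise
    naturally; ``force_pseudoknot`` redraws the map until two helices
    interleave.  Token composition is biased towards specific classes so
    that random backgrounds are not saturated with matches.
    """
    n_el = int(rng.integers(n_elements[0], n_elements[1] + 1))
    n_helix = int(rng.integers(1, max(2, n_el // 2) + 1))
    if force_pseudoknot:
        n_helix = max(2, n_helix)
    n_single = n_el - n_helix
    if n_single < 0:
        n_helix, n_single = n_el, 0

    def draw_map() -> list[str]:
        slots: list[str] = [f"s{i + 1}" for i in range(n_single)]
        for k in range(n_helix):
            slots += [f"h{k + 1}", f"h{k + 1}'"]
        while True:
            order = list(rng.permutation(len(slots)))
            occ = [slots[i] for i in order]
            ok = all(
                occ.index(f"h{k + 1}") < occ.index(f"h{k + 1}'")
                for k in range(n_helix)
            )
            if ok:
                return occ

    def interleaved(occ: list[str]) -> bool:
        for a in range(1, n_helix + 1):
            for b in range(1, n_helix + 1):
                if a == b:
                    continue
                a1, a2 = occ.index(f"h{a}"), occ.index(f"h{a}'")
                b1 = occ.index(f"h{b}")
                if a1 < b1 < a2 < occ.index(f"h{b}'"):
                    return True
        return False

    occ = draw_map()
    if force_pseudoknot:
        for _ in range(200):
            if interleaved(occ):
                break
            occ = draw_map()

    token_pool = list("ACGT") * 5 + list("RYSWKM") * 2 + ["N"] * 3 + [WILDCARD] * 2

    def draw_tokens(lo: int, hi: int, allow_wild: bool = True) -> str:
        ln = int(rng.integers(lo, hi + 1))
        toks = []
        for _ in range(ln):
            t = token_pool[int(rng.integers(len(token_pool)))]
            if not allow_wild and t == WILDCARD:
                t = "N"
            toks.append(t)
        if all(t == WILDCARD for t in toks):
            toks[0] = "N"  # keep at least one mandatory token
        return "".join(toks)

    specs: dict[str, object] = {}
    for i in range(n_single):
        tag = f"s{i + 1}"
        m = int(rng.integers(0, max_budget + 1)) if rng.random() < 0.4 else 0
        ins = int(rng.integers(0, max_budget + 1)) if rng.random() < 0.3 else 0
        specs[tag] = SingleStrandSpec(
            tag, tuple(draw_tokens(2, max_strand_len)), m, ins
        )
    for k in range(n_helix):
        tag = f"h{k + 1}"
        ncol = int(rng.integers(2, max_strand_len + 1))
        t5, t3 = [], []
        for _ in range(ncol):
            if rng.random() < 0.15:
                t5.append(WILDCARD)
                t3.append(WILDCARD)
            else:
                t5.append(token_pool[int(rng.integers(len(token_pool) - 2))])
                t3.append(token_pool[int(rng.integers(len(token_pool) - 2))])
        if all(t == WILDCARD for t in t5):
            t5[0] = t3[0] = "N"
        pairs = (
            frozenset({"AT", "TA", "CG", "GC", "GT", "TG"})
            if rng.random() < 0.3
            else frozenset({"AT", "TA", "CG", "GC"})
        )
        m = int(rng.integers(0, max_budget + 1)) if rng.random() < 0.3 else 0
        r = int(rng.integers(0, max_budget + 1)) if rng.random() < 0.4 else 0
        ins = int(rng.integers(0, max_budget + 1)) if rng.random() < 0.3 else 0
        hx = HelixSpec(tag, tuple(t5), tuple(t3), pairs, m, r, ins)
        # drop unmatchable columns by widening the pair set
        try:
            hx.validate_matchable()
        except Exception:
            hx = HelixSpec(
                tag, tuple(t5), tuple(t3), pairs, m, max(r, 1), ins
            )
        specs[tag] = hx
    return Descriptor(MotifMap(tuple(occ)), specs, None, "random")


def random_search_instance(
    rng: np.random.Generator,
    min_len: int = 100,
    max_len: int = 200,
    embed_probability: float = 0.7,
    **descriptor_kwargs,
) -> tuple[Descriptor, str]:
    """A random (descriptor, sequence) pair for equivalence sweeps.

    With probability ``embed_probability`` one sampled occurrence is
    embedded in the otherwise uniform background, so positive cases are
    exercised as well as negatives.
    """
    d = random_descriptor(rng, **descriptor_kwargs)
    n = int(rng.integers(min_len, max_len + 1))
    text = "".join(rng.choice(list(_BASES), size=n))
    if rng.random() < embed_probability:
        try:
            s, _ = sample_occurrence(d, rng)
            if len(s) < n:
                pos = int(rng.integers(0, n - len(s) + 1))
                text = text[:pos] + s + text[pos + len(s):]
        except ValueError:
            pass
    return d, text


# ---------------------------------------------------------------------------
# Planted sequences.


@dataclass(frozen=True)
class PlantedTruth:
    """A synthetic sequence with motif occurrences at known coordinates."""

    seq_id: str
    sequence: str
    #: per plant: (interval tuple over map occurrences, planted string)
    plants: tuple[tuple[tuple[tuple[int, int], ...], str], ...]

    def spans(self) -> list[tuple[int, int]]:
        out = []
        for intervals, _ in self.plants:
            out.append((min(s for s, _ in intervals), max(e for _, e in intervals)))
        return out

    def to_fasta(self) -> str:
        lines = [f">{self.seq_id}"]
        for i in range(0, len(self.sequence), 70):
            lines.append(self.sequence[i:i + 70])
        return "\n".join(lines) + "\n"

    def truth_tsv(self) -> str:
        """BED-like ground truth (1-based inclusive span coordinates)."""
        rows = ["#seq_id\tspan_start\tspan_end\tplanted_sequence"]
        for (intervals, s) in self.plants:
            lo = min(a for a, _ in intervals)
            hi = max(b for _, b in intervals)
            rows.append(f"{self.seq_id}\t{lo + 1}\t{hi}\t{s}")
        return "\n".join(rows) + "\n"


def sample_occurrence(
    descriptor: Descriptor,
    rng: np.random.Generator,
    budgets_used: dict[str, dict[str, int]] | None = None,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Sample one concrete realization of the motif.

    Class positions draw from their base sets, wildcard tokens are kept
    with probability 1/2, helix columns draw from the allowed pairs
    compatible with both classes.  ``budgets_used`` may force distortions,
    e.g. ``{"s1": {"mismatch": 1}, "h2": {"insert": 1}}``; a forced
    mismatch at an element with no mismatchable position raises.
    Returns the concatenated string and 0-based intervals per occurrence.
    """
    forced = budgets_used or {}
    chunks: dict[str, str] = {}
    for tag in descriptor.map.element_tags:
        spec = descriptor.specs[tag]
        want = forced.get(tag, {})
        if spec.is_helix:
            c5, c3 = _sample_helix(spec, rng, want)
            chunks[tag] = c5
            chunks[tag + "'"] = c3
        else:
            chunks[tag] = _sample_single(spec, rng, want)
    parts, intervals, pos = [], {}, 0
    for occ in descriptor.map.occurrences:
        s = chunks[occ]
        intervals[occ] = (pos, pos + len(s))
        parts.append(s)
        pos += len(s)
    return "".join(parts), intervals


def _sample_single(
    spec: SingleStrandSpec, rng: np.random.Generator, want: dict[str, int]
) -> str:
    n_mm = want.get("mismatch", 0)
    n_ins = want.get("insert", 0)
    if n_mm > spec.max_mismatch or n_ins > spec.max_insert:
        raise ValueError(f"{spec.tag}: forced distortions exceed budgets")
    mandatory = [j for j, t in enumerate(spec.tokens) if t != WILDCARD]
    mismatchable = [
        j for j in mandatory if len(IUPAC_BASES[spec.tokens[j]]) < 4
    ]
    if n_mm > len(mismatchable):
        raise ValueError(f"{spec.tag}: cannot force {n_mm} mismatches")
    mm_at = set(
        rng.choice(mismatchable, size=n_mm, replace=False)
    ) if n_mm else set()
    out = []
    junction_offset = {}  # token junction p -> offset in the emitted string
    for j, t in enumerate(spec.tokens):
        if j >= 1:
            junction_offset[j] = len(out)
        if t == WILDCARD:
            if rng.random() < 0.5:
                out.append(_BASES[int(rng.integers(4))])
        else:
            bs = sorted(IUPAC_BASES[t])
            if j in mm_at:
                bs = sorted(set(_BASES) - set(bs))
            out.append(bs[int(rng.integers(len(bs)))])
    plen = len(spec.tokens)
    if n_ins:
        if plen < 2:
            raise ValueError(f"{spec.tag}: no internal junction for insertions")
        # insertions sit at internal junctions (before tokens 1..plen-1);
        # insert right-to-left so earlier offsets stay valid
        junctions = sorted(
            (int(rng.integers(1, plen)) for _ in range(n_ins)), reverse=True
        )
        for p in junctions:
            out.insert(junction_offset[p], _BASES[int(rng.integers(4))])
    return "".join(out)


def _sample_helix(
    spec: HelixSpec, rng: np.random.Generator, want: dict[str, int]
) -> tuple[str, str]:
    n_mp = want.get("mispair", 0)
    n_ins = want.get("insert", 0)
    if n_mp > spec.max_mispair or n_ins > spec.max_insert:
        raise ValueError(f"{spec.tag}: forced distortions exceed budgets")
    cols: list[tuple[str, str] | None] = []
    mandatory_idx = []
    for j in range(spec.n_columns):
        if spec.base_sets5[j] is None:
            if rng.random() < 0.5:
                cols.append(None)
                continue
        mandatory_idx.append(len(cols))
        c5 = spec.base_sets5[j] or IUPAC_BASES["N"]
        c3 = spec.base_sets3[j] or IUPAC_BASES["N"]
        ok = sorted(
            p for p in spec.allowed_pairs if p[0] in c5 and p[1] in c3
        )
        if not ok:
            raise ValueError(f"{spec.tag}: column {j + 1} unsatisfiable")
        cols.append(tuple(ok[int(rng.integers(len(ok)))]))
    kept = [c for c in cols if c is not None]
    if n_mp:
        if n_mp > len(kept):
            raise ValueError(f"{spec.tag}: cannot force {n_mp} mispairs")
        for idx in rng.choice(len(kept), size=n_mp, replace=False):
            j_real = [i for i, c in enumerate(cols) if c is not None][idx]
            s5 = sorted(spec.base_sets5[j_real] or IUPAC_BASES["N"])
            s3 = sorted(spec.base_sets3[j_real] or IUPAC_BASES["N"])
            broken = [
                (x, y) for x in s5 for y in s3 if x + y not in spec.allowed_pairs
            ]
            if not broken:
                raise ValueError(f"{spec.tag}: cannot break column {j_real + 1}")
            cols[j_real] = broken[int(rng.integers(len(broken)))]
    strand5 = [c[0] for c in cols if c is not None]
    strand3 = [c[1] for c in cols if c is not None]  # outside-in order
    if n_ins:
        if len(strand5) < 2:
            raise ValueError(f"{spec.tag}: helix too short for bulges")
        junctions = [int(j) for j in rng.permutation(range(1, len(strand5)))]
        for jj, which in zip(
            sorted(junctions[:n_ins], reverse=True), rng.integers(0, 2, size=n_ins)
        ):
            base = _BASES[int(rng.integers(4))]
            if which == 0:
                strand5.insert(jj, base)
            else:
                strand3.insert(jj, base)
    return "".join(strand5), "".join(reversed(strand3))


def generate_planted_sequence(
    descriptor: Descriptor,
    length: int,
    n_plants: int,
    rng: np.random.Generator,
    gc: float = 0.5,
    seq_id: str = "synthetic",
    max_tries: int = 200,
) -> PlantedTruth:
    """An i.i.d. background sequence with non-overlapping planted occurrences."""
    if length < n_plants * descriptor.L:
        raise ValueError("sequence too short for the requested plants")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list(rng.choice(list(_BASES), size=length, p=p))
    plants = []
    taken: list[tuple[int, int]] = []
    for _ in range(n_plants):
        s, intervals = sample_occurrence(descriptor, rng)
        for _try in range(max_tries):
            pos = int(rng.integers(0, length - len(s) + 1))
            if all(pos + len(s) <= a or pos >= b for a, b in taken):
                break
        else:
            raise ValueError("could not place plants without overlap")
        taken.append((pos, pos + len(s)))
        seq[pos:pos + len(s)] = list(s)
        abs_intervals = tuple(
            (intervals[occ][0] + pos, intervals[occ][1] + pos)
            for occ in descriptor.map.occurrences
        )
        plants.append((abs_intervals, s))
    return PlantedTruth(seq_id, "".join(seq), tuple(plants))
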