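"""Dynamic-programming matchers against exhaustive alignment enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnarobo.descriptor import HelixSpec, SingleStrandSpec
from rnarobo.fixtures import _hx_distortion_set, _ss_distortion_set
from rnarobo.matcher import (
    HelixMatch,
    SearchDomain,
    SingleMatch,
    match_helix,
    match_single,
    prefilter_positions,
)

GU = frozenset({"AT", "TA", "CG", "GC", "GT", "TG"})


def _oracle_single(spec, text, domain):
    """Enumerate every interval and alignment; minimal counts per interval."""
    out = {}
    for s in range(len(text) + 1):
        for e in range(s, len(text) + 1):
            dists = {
                (mm, ins)
                for mm, ins in _ss_distortion_set(spec, text[s:e])
                if mm <= spec.max_mismatch and ins <= spec.max_insert
            }
            if dists and domain.admits(s, e):
                out[(s, e)] = min(dists)
    return {
        SingleMatch(s, e, mm, ins) for (s, e), (mm, ins) in out.items()
    }


def _oracle_helix(spec, text, dom5, dom3, gap=None):
    out = {}
    n = len(text)
    for a in range(n + 1):
        for e5 in range(a, n + 1):
            for s3 in range(e5, n + 1):
                for d in range(s3, n + 1):
                    if gap is not None and not (gap[0] <= s3 - e5 <= gap[1]):
                        continue
                    if not (dom5.admits(a, e5) and dom3.admits(s3, d)):
                        continue
                    dists = _hx_distortion_set(spec, text[a:e5], text[s3:d])
                    if dists:
                        out[(a, e5, s3, d)] = min(dists)
    return {
        HelixMatch(a, e5, s3, d, mm, mp, ins)
        for (a, e5, s3, d), (mm, mp, ins) in out.items()
    }


def _random_single_spec(rng, max_len=6, max_budget=2):
    pool = list("ACGT") * 4 + list("RYSN") + ["*"]
    ln = int(rng.integers(1, max_len + 1))
    toks = [pool[int(rng.integers(len(pool)))] for _ in range(ln)]
    if all(t == "*" for t in toks):
        toks[0] = "N"
    return SingleStrandSpec(
        "s1",
        tuple(toks),
        int(rng.integers(0, max_budget + 1)),
        int(rng.integers(0, max_budget + 1)),
    )


def _random_helix_spec(rng, max_cols=5, max_budget=2):
    pool = list("ACGT") * 3 + list("RYN")
    ncol = int(rng.integers(1, max_cols + 1))
    t5, t3 = [], []
    for _ in range(ncol):
        if rng.random() < 0.2:
            t5.append("*")
            t3.append("*")
        else:
            t5.append(pool[int(rng.integers(len(pool)))])
            t3.append(pool[int(rng.integers(len(pool)))])
    if all(t == "*" for t in t5):
        t5[0] = t3[0] = "N"
    return HelixSpec(
        "h1",
        tuple(t5),
        tuple(t3),
        GU if rng.random() < 0.3 else frozenset({"AT", "TA", "CG", "GC"}),
        int(rng.integers(0, max_budget + 1)),
        int(rng.integers(0, max_budget + 1)),
        int(rng.integers(0, max_budget + 1)),
    )


def _random_text(rng, lo=5, hi=25):
    n = int(rng.integers(lo, hi + 1))
    return "".join(
        rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04])
    )


# ---------------------------------------------------------------------------
# Worked examples.


@pytest.mark.parametrize(
    "tokens,m,i,text,expected",
    [
        ("ACG", 0, 0, "TACGT", {(1, 4, 0, 0)}),
        ("A", 1, 0, "TTTT", {(0, 1, 1, 0), (1, 2, 1, 0), (2, 3, 1, 0), (3, 4, 1, 0)}),
        ("A*", 0, 0, "AG", {(0, 1, 0, 0), (0, 2, 0, 0)}),
        # internal insertion between the two tokens
        ("AG", 0, 1, "ACG", {(0, 3, 0, 1)}),
        # insertions are internal: no match by appending at a flank
        ("AG", 0, 1, "AGT", {(0, 2, 0, 0)}),
    ],
)
def test_single_strand_examples(tokens, m, i, text, expected):
    got = match_single(
        SingleStrandSpec("s1", tuple(tokens), m, i), text, SearchDomain.full(len(text))
    )
    assert {(x.start, x.end, x.mismatches_used, x.insertions_used) for x in got} == expected


def test_helix_example_watson_crick():
    spec = HelixSpec("h1", tuple("NN"), tuple("NN"))
    dom5, dom3 = SearchDomain((0, 1), (0, 2)), SearchDomain((2, 3), (2, 4))
    got = match_helix(spec, "ACGT", dom5, dom3)
    assert [(m.start5, m.end5, m.start3, m.end3) for m in got] == [(0, 2, 2, 4)]
    assert match_helix(spec, "ACCT", dom5, dom3) == []
    relaxed = HelixSpec("h1", tuple("NN"), tuple("NN"), max_mispair=1)
    got = match_helix(relaxed, "ACCT", dom5, dom3)
    assert [(m.start5, m.end5, m.start3, m.end3, m.mispairs_used) for m in got] == [
        (0, 2, 2, 4, 1)
    ]


def test_helix_bulge_insertion_not_adjacent():
    # one bulge allowed between columns; two in a row are not
    spec = HelixSpec("h1", tuple("NNN"), tuple("NNN"), max_insert=1)
    # 5' strand A(G)AC with a bulged G pairs 3' strand GTT (read in text order)
    text = "AGACAAAGTT"
    got = match_helix(
        spec, text, SearchDomain((0, 0), (4, 4)), SearchDomain((7, 7), (10, 10))
    )
    assert got == [HelixMatch(0, 4, 7, 10, 0, 0, 1)]
    # two bulges would have to sit at distinct junctions, never back to back
    two = HelixSpec("h1", tuple("NN"), tuple("NN"), max_insert=2)
    text2 = "AGGACT"  # would need two adjacent bulges GG inside the 5' strand
    got2 = match_helix(
        two, text2, SearchDomain((0, 0), (4, 4)), SearchDomain((4, 4), (6, 6))
    )
    assert got2 == []


def test_empty_domain_yields_nothing():
    spec = SingleStrandSpec("s1", tuple("A"))
    dom = SearchDomain((3, 2), (3, 2))
    assert match_single(spec, "AAAA", dom) == []
    assert prefilter_positions(spec, "AAAA", dom) == set()


def test_text_n_matches_only_full_class():
    full = SingleStrandSpec("s1", tuple("N"))
    strict = SingleStrandSpec("s1", tuple("A"))
    assert match_single(full, "N", SearchDomain.full(1)) == [SingleMatch(0, 1)]
    assert match_single(strict, "N", SearchDomain.full(1)) == []
    # chargeable as a mismatch
    lax = SingleStrandSpec("s1", tuple("A"), 1, 0)
    assert match_single(lax, "N", SearchDomain.full(1)) == [SingleMatch(0, 1, 1, 0)]


# ---------------------------------------------------------------------------
# Oracle equivalence, minimality, monotonicity (property sweeps).


def test_single_matches_exhaustive_enumeration(rng):
    for _ in range(150):
        spec = _random_single_spec(rng)
        text = _random_text(rng)
        n = len(text)
        if rng.random() < 0.5:
            dom = SearchDomain.full(n)
        else:
            s = sorted(rng.integers(0, n + 1, size=2))
            e = sorted(rng.integers(0, n + 1, size=2))
            dom = SearchDomain((int(s[0]), int(s[1])), (int(e[0]), int(e[1])))
        assert set(match_single(spec, text, dom)) == _oracle_single(spec, text, dom)


def test_helix_matches_exhaustive_enumeration(rng):
    for _ in range(60):
        spec = _random_helix_spec(rng)
        text = _random_text(rng, 4, 14)
        n = len(text)
        dom5 = SearchDomain.full(n)
        dom3 = SearchDomain.full(n)
        gap = None
        if rng.random() < 0.5:
            g0 = int(rng.integers(0, 4))
            gap = (g0, g0 + int(rng.integers(0, 4)))
        assert set(match_helix(spec, text, dom5, dom3, gap)) == _oracle_helix(
            spec, text, dom5, dom3, gap
        )


def test_budget_monotonicity(rng):
    for _ in range(60):
        spec = _random_single_spec(rng, max_budget=1)
        text = _random_text(rng)
        dom = SearchDomain.full(len(text))
        base = {(m.start, m.end) for m in match_single(spec, text, dom)}
        grown = SingleStrandSpec(
            spec.tag, spec.tokens, spec.max_mismatch + 1, spec.max_insert + 1
        )
        more = {(m.start, m.end) for m in match_single(grown, text, dom)}
        assert base <= more


def test_domain_soundness(rng):
    for _ in range(60):
        spec = _random_single_spec(rng)
        text = _random_text(rng)
        n = len(text)
        s = sorted(rng.integers(0, n + 1, size=2))
        e = sorted(rng.integers(0, n + 1, size=2))
        c = sorted(rng.integers(0, n + 1, size=2))
        dom = SearchDomain(
            (int(s[0]), int(s[1])), (int(e[0]), int(e[1])), (int(c[0]), int(c[1]))
        )
        for m in match_single(spec, text, dom):
            assert dom.admits(m.start, m.end)


def test_match_sets_are_sorted(rng):
    for _ in range(20):
        spec = _random_single_spec(rng)
        text = _random_text(rng)
        got = match_single(spec, text, SearchDomain.full(len(text)))
        assert got == sorted(got)


# ---------------------------------------------------------------------------
# Prefilter contract.


def test_prefilter_superset_and_equivalence(rng):
    for _ in range(150):
        spec = _random_single_spec(rng)
        text = _random_text(rng)
        dom = SearchDomain.full(len(text))
        plain = match_single(spec, text, dom)
        assert match_single(spec, text, dom, prefilter=True) == plain
        ends = prefilter_positions(spec, text, dom)
        assert {m.end for m in plain} <= ends


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    pattern=st.lists(
        st.sampled_from(list("ACGTRYN*")), min_size=1, max_size=5
    ).filter(lambda t: any(c != "*" for c in t)),
    text=st.text(alphabet="ACGT", min_size=0, max_size=15),
    m=st.integers(0, 2),
    i=st.integers(0, 2),
)
def test_single_matcher_equals_enumeration_hypothesis(pattern, text, m, i):
    spec = SingleStrandSpec("s1", tuple(pattern), m, i)
    dom = SearchDomain.full(len(text))
    assert set(match_single(spec, text, dom)) == _oracle_single(spec, text, dom)


def test_prefilter_exact_pattern_example():
    spec = SingleStrandSpec("s1", tuple("ACG"))
    ends = prefilter_positions(spec, "TACGT", SearchDomain.full(5))
    assert 4 in ends
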