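"""Information-content heuristics, candidate proposal and DDEO elimination."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rnarobo import ordering
from rnarobo.descriptor import (
    HelixSpec,
    SingleStrandSpec,
    parse_descriptor,
)
from rnarobo.fixtures import _ss_distortion_set, hdv_like
from rnarobo.ordering import (
    DdeoController,
    HeuristicWeights,
    OrderCandidate,
    ddeo_controller,
    h1,
    h1_helix,
    h1_single,
    h2_flex,
    heuristic_order,
    log2_upper_bound_count,
    propose_candidates,
    score_tuple,
    welch_one_sided,
)

GU = frozenset({"AT", "TA", "CG", "GC", "GT", "TG"})


# ---------------------------------------------------------------------------
# h1 closed forms.


@pytest.mark.parametrize(
    "tokens,expected",
    [
        ("AAAA", 8.0),
        ("NNN", 0.0),
        ("A**", 6 - math.log2(48)),
    ],
)
def test_h1_single_closed_forms(tokens, expected):
    assert h1_single(SingleStrandSpec("s1", tuple(tokens))) == pytest.approx(
        expected, abs=1e-12
    )


def test_h1_helix_closed_forms():
    assert h1_helix(HelixSpec("h1", tuple("NNNN"), tuple("NNNN"))) == pytest.approx(8.0)
    assert h1_helix(
        HelixSpec("h1", tuple("NNNN"), tuple("NNNN"), GU)
    ) == pytest.approx(16 - 4 * math.log2(6), abs=1e-12)
    assert h1_helix(HelixSpec("h1", tuple("GGGG"), tuple("CCCC"))) == pytest.approx(16.0)


def test_h1_extremes_property(rng):
    # fully specified strand of length N scores exactly 2N; all-N exactly 0
    for n in range(1, 9):
        toks = tuple(
            "ACGT"[int(i)] for i in rng.integers(0, 4, size=n)
        )
        assert h1_single(SingleStrandSpec("s1", toks)) == pytest.approx(2.0 * n)
        assert h1_single(SingleStrandSpec("s1", ("N",) * n)) == pytest.approx(0.0)


def _exact_match_count(spec):
    """Enumerate all sequences of maximal length with a match at position 1."""
    n = spec.max_len
    count = 0
    for seq in itertools.product("ACGT", repeat=n):
        s = "".join(seq)
        if any(
            any(
                mm <= spec.max_mismatch and ins <= spec.max_insert
                for mm, ins in _ss_distortion_set(spec, s[:ln])
            )
            for ln in range(spec.min_len, spec.max_len + 1)
        ):
            count += 1
    return count


def test_wildcard_bound_exceeds_exact_enumeration():
    spec = SingleStrandSpec("s1", tuple("A**"))
    exact = _exact_match_count(spec)
    assert exact == 16
    assert 2 ** log2_upper_bound_count(spec) == pytest.approx(48)
    assert 48 >= exact


def test_upper_bound_holds_on_element_grid():
    # X_U >= exact X for every zero-mismatch element on a small grid
    patterns = [
        "A", "AC", "RY", "N*", "A*C", "**A", "AN*G", "R*YN", "ACG*",
        "SWK", "A**T",
    ]
    for pat, ins in itertools.product(patterns, (0, 1, 2)):
        spec = SingleStrandSpec("s1", tuple(pat), 0, ins)
        exact = _exact_match_count(spec)
        bound = 2 ** log2_upper_bound_count(spec)
        assert bound >= exact - 1e-6, (pat, ins, exact, bound)


def test_bound_monotone_in_budgets_and_classes():
    base = SingleStrandSpec("s1", tuple("ACGT"))
    for m, i in [(1, 0), (0, 1), (2, 2)]:
        assert log2_upper_bound_count(
            SingleStrandSpec("s1", tuple("ACGT"), m, i)
        ) >= log2_upper_bound_count(base)
    assert log2_upper_bound_count(
        SingleStrandSpec("s1", tuple("NCGT"))
    ) >= log2_upper_bound_count(base)
    hx = HelixSpec("h1", tuple("AC"), tuple("GT"))
    for m, r, i in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
        assert log2_upper_bound_count(
            HelixSpec("h1", tuple("AC"), tuple("GT"), max_mismatch=m,
                      max_mispair=r, max_insert=i)
        ) >= log2_upper_bound_count(hx)
    assert log2_upper_bound_count(
        HelixSpec("h1", tuple("AC"), tuple("GT"), GU)
    ) >= log2_upper_bound_count(hx)


# ---------------------------------------------------------------------------
# h2 flexibility.


@pytest.fixture
def flex_map():
    # flexibilities: s1=0, s2=3, s3=0, s4=1, s5=0
    return parse_descriptor(
        """s1 s2 s3 s4 s5
s1 0:0 GGGG
s2 0:0 N***
s3 0:0 NN
s4 0:0 NN*
s5 0:0 CCCC
"""
    )


def test_h2_both_sides_fixed_takes_min(flex_map):
    assert h2_flex(flex_map, ["s1", "s5"], "s3") == 1


def test_h2_one_side_fixed(flex_map):
    assert h2_flex(flex_map, ["s1"], "s3") == 3


def test_h2_empty_prefix_is_zero(flex_map):
    assert h2_flex(flex_map, [], "s3") == 0
    assert h2_flex(hdv_like(), [], "h2") == 0


def test_h2_helix_takes_max_over_strands():
    d = parse_descriptor(
        """s1 h1 s2 h1' s3
s1 0:0 AAAA
s2 0:0 N***
s3 0:0 NN*
h1 0:0:0 NN:NN
"""
    )
    # 5' strand: abuts fixed s1 on the left (0), sibling across s2 on the
    # right (3) -> min 0.  3' strand: sibling across s2 on the left (3),
    # nothing fixed to the right -> 3.  Helix takes the max of the strands.
    assert h2_flex(d, ["s1"], "h1") == 3


# ---------------------------------------------------------------------------
# Tuple scoring and candidate proposal.


def test_score_tuple_worked_example(monkeypatch):
    # abstract plug-in: three single strands with (h1, h2) = (8,0),(6,2),(4,5)
    d = parse_descriptor(
        "s1 s2 s3\ns1 0:0 AAAA\ns2 0:0 AAA\ns3 0:0 AA\n"
    )
    h1_vals = {"s1": 8.0, "s2": 6.0, "s3": 4.0}
    h2_vals = {"s1": 0, "s2": 2, "s3": 5}
    monkeypatch.setattr(ordering, "h1", lambda spec: h1_vals[spec.tag])
    monkeypatch.setattr(
        ordering, "h2_flex", lambda desc, prefix, tag: h2_vals[tag]
    )
    got = score_tuple(d, ["s1", "s2", "s3"])
    assert got == pytest.approx(142.2, abs=1e-9)


def test_score_tuple_short_tuple_uses_high_weights():
    d = parse_descriptor("s1 s2\ns1 0:0 AAAA\ns2 0:0 CC\n")
    # k=3 but only 2 elements: weights 4 and 2 on the 2-tuple
    got = score_tuple(d, ["s1", "s2"])
    expected = 4 * (3 * 8.0) + 2 * (3 * 4.0 + (-0.2) * 0)
    assert got == pytest.approx(expected)


def test_score_tuple_symmetric_under_equal_elements():
    d = parse_descriptor("s1 s2 s3\ns1 0:0 AAAA\ns2 0:0 TTTT\ns3 0:0 GGGG\n")
    w = HeuristicWeights()
    assert score_tuple(d, ["s1", "s2"], w) == pytest.approx(
        score_tuple(d, ["s2", "s1"], w)
    )


def test_propose_candidates_threshold_and_completion():
    d = hdv_like()
    w = HeuristicWeights()
    cands = propose_candidates(d, w)
    assert 1 <= len(cands) <= w.max_candidates
    scores = [c.score for c in cands]
    tags = set(d.map.element_tags)
    assert all(s >= w.keep_fraction * max(scores) - 1e-9 for s in scores)
    for c in cands:
        assert len(c.prefix) == w.k
        assert set(c.full_order) == tags
        assert c.full_order[: w.k] == c.prefix
    # completion appends the remaining elements by decreasing h1
    tail = cands[0].full_order[w.k:]
    h1s = [h1(d.specs[t]) for t in tail]
    assert h1s == sorted(h1s, reverse=True)


def test_propose_candidates_cap_at_50():
    # 6 interchangeable elements: P(6,3) = 120 equal-scoring tuples
    lines = ["s1 s2 s3 s4 s5 s6"] + [f"s{i} 0:0 NN" for i in range(1, 7)]
    d = parse_descriptor("\n".join(lines) + "\n")
    cands = propose_candidates(d, HeuristicWeights())
    assert len(cands) == 50


def test_heuristic_order_prefers_specific_singles():
    d = hdv_like()
    order = heuristic_order(d)
    assert order[0] == "s3"  # the conserved 9-mer dominates every tuple


# ---------------------------------------------------------------------------
# Welch's t-test.


def test_welch_identical_samples_is_neutral():
    assert welch_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)
    assert welch_one_sided([2.0, 2.0], [2.0, 2.0]) == 0.5
    assert welch_one_sided([1.0], [1.0, 2.0]) == 0.5


def test_welch_separated_samples_significant():
    assert welch_one_sided([10, 12, 14], [20, 22, 24]) < 0.01


def test_welch_one_sided_symmetry():
    x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
    assert welch_one_sided(x, y) + welch_one_sided(y, x) == pytest.approx(1.0)


def test_welch_agrees_with_scipy_oracle(rng):
    for _ in range(100):
        nx, ny = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        x = rng.normal(rng.uniform(0, 5), rng.uniform(0.5, 2), size=nx)
        y = rng.normal(rng.uniform(0, 5), rng.uniform(0.5, 2), size=ny)
        ours = welch_one_sided(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False, alternative="less").pvalue
        assert ours == pytest.approx(ref, abs=1e-6)


# ---------------------------------------------------------------------------
# DDEO controller.


def _two_candidate_controller(seed, mean_a=1.0, sd_a=0.1, mean_b=10.0, sd_b=1.0):
    d = parse_descriptor(
        "s1 h1 h1'\ns1 0:0 AATT\nh1 0:0:0 NNN:NNN\n"
    )
    rng = np.random.default_rng(seed)
    noise = np.random.default_rng(seed + 10_000)
    a = OrderCandidate(("s1", "h1"), ("s1", "h1"))
    b = OrderCandidate(("h1", "s1"), ("h1", "s1"))

    def stub(order, text):
        if order[0] == "s1":
            return abs(noise.normal(mean_a, sd_a))
        return abs(noise.normal(mean_b, sd_b))

    return d, DdeoController(
        d, HeuristicWeights(), rng, timing_source=stub, candidates=[a, b]
    )


def test_ddeo_eliminates_slow_candidate():
    wins = 0
    for seed in range(100):
        d, ctl = _two_candidate_controller(seed)
        for _ in range(200):
            if ctl.settled:
                break
            ctl.run_window("ACGTAATTACGT")
        if ctl.final_order[0] == "s1":
            wins += 1
    assert wins >= 95


def test_ddeo_identical_timings_still_terminates():
    d, ctl = _two_candidate_controller(3, mean_a=1.0, sd_a=0.2, mean_b=1.0, sd_b=0.2)
    for _ in range(1000):
        if ctl.settled:
            break
        ctl.run_window("ACGTAATTACGT")
    assert ctl.settled
    assert set(ctl.final_order) == {"s1", "h1"}


def test_ddeo_is_reproducible_given_seed():
    orders = set()
    for _ in range(3):
        d, ctl = _two_candidate_controller(7)
        for _ in range(300):
            if ctl.settled:
                break
            ctl.run_window("ACGTAATTACGT")
        orders.add(ctl.final_order)
    assert len(orders) == 1


def test_ddeo_occurrences_match_fixed_order(rng):
    from rnarobo.engine import backtrack_window
    from rnarobo.fixtures import generate_planted_sequence

    d = hdv_like()
    truth = generate_planted_sequence(d, 4000, 2, rng, seq_id="sim")
    windows = [truth.sequence[s:e] for s, e in [(0, 2000), (2000, 4000)]]
    # plants may straddle the artificial cut; regenerate windows from spans
    windows = [truth.sequence]
    final, found = ddeo_controller(
        d, windows * 3, HeuristicWeights(), np.random.default_rng(0)
    )
    fixed = backtrack_window(truth.sequence, d, list(d.map.element_tags))
    assert found == fixed
    assert set(final) == set(d.map.element_tags)


def test_single_element_needs_no_sampling():
    d = parse_descriptor("s1\ns1 0:0 ACGT\n")
    ctl = DdeoController(d, HeuristicWeights(), np.random.default_rng(0))
    assert ctl.settled
    assert ctl.final_order == ("s1",)
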