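from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songrhythm import (
    BIN_LABELS,
    IOISequence,
    classify_ratio,
    compute_iois,
    compute_ratios,
    compute_triples,
    count_bins,
    default_bin_scheme,
)

from conftest import make_contribution


def brute_force_classify(r: float) -> str | None:
    """Independent comparator against the literal fractional boundaries."""
    b = [
        1 / 3.5, 1 / 3.25, 1 / 2.75, 1 / 2.5, 1 / 2.25,
        1 - 1 / 2.25, 1 - 1 / 2.5, 1 - 1 / 2.75, 1 - 1 / 3.25, 1 - 1 / 3.5,
    ]
    labels = [
        "off_R12", "on_R12", "off_R12", "off_R11", "on_R11",
        "off_R11", "off_R21", "on_R21", "off_R21",
    ]
    if r < b[0] or r > b[-1]:
        return None
    if r == b[-1]:
        return "off_R21"
    for lo, hi, lab in zip(b, b[1:], labels):
        if lo <= r < hi:
            return lab
    return None


class TestIOIs:
    def test_plain_differences(self):
        iois = compute_iois(make_contribution([0, 2, 4]))
        assert iois.values == (2, 2)
        assert iois.break_after == frozenset()

    def test_over_cap_interval_discarded_with_break(self):
        iois = compute_iois(make_contribution([0, 2, 9, 11]))
        assert iois.values == (2, 2)
        assert iois.break_after == frozenset({0})

    def test_bridge_gaps_flag_removes_only_the_interval(self):
        iois = compute_iois(make_contribution([0, 2, 9, 11]), bridge_gaps=True)
        assert iois.values == (2, 2)
        assert iois.break_after == frozenset()

    def test_single_onset_yields_empty_sequence(self):
        iois = compute_iois(make_contribution([1.0]))
        assert len(iois) == 0

    def test_non_increasing_onsets_rejected(self):
        with pytest.raises(ValueError):
            compute_iois([0.0, 2.0, 1.0])

    def test_custom_cap(self):
        iois = compute_iois(make_contribution([0, 2, 5.5]), cap=3.0)
        assert iois.values == (2,)


class TestRatios:
    def test_isochrony_gives_half(self):
        assert compute_ratios(IOISequence((2.0, 2.0), frozenset())) == [0.5]

    def test_double_duration_gives_one_third(self):
        (r,) = compute_ratios(IOISequence((1.0, 2.0), frozenset()))
        assert r == pytest.approx(1 / 3, abs=1e-15)

    def test_no_ratio_across_break(self):
        iois = IOISequence((2.0, 2.0, 3.0, 3.0), frozenset({1}))
        assert compute_ratios(iois) == [0.5, 0.5]

    def test_matches_bruteforce_over_runs(self):
        rng = np.random.default_rng(42)
        vals = tuple(rng.uniform(0.5, 4.5, size=30))
        breaks = frozenset({4, 11, 12, 20})
        iois = IOISequence(vals, breaks)
        expected = []
        for run in iois.runs():
            for a, b in zip(run, run[1:]):
                expected.append(a / (a + b))
        assert compute_ratios(iois) == expected

    def test_empty_input_empty_output(self):
        assert compute_ratios(IOISequence((), frozenset())) == []


class TestBinScheme:
    def test_on_ranges_are_the_exact_fractions(self):
        s = default_bin_scheme()
        assert s.on_range("R12") == (Fraction(4, 13), Fraction(4, 11))
        assert s.on_range("R11") == (Fraction(4, 9), Fraction(5, 9))
        assert s.on_range("R21") == (Fraction(7, 11), Fraction(9, 13))

    def test_ranges_tile_the_span_contiguously(self):
        s = default_bin_scheme()
        assert s.span == (Fraction(2, 7), Fraction(5, 7))
        edges = []
        for cat in ("R12", "R11", "R21"):
            left_lo, on_lo, on_hi, right_hi = s.ranges[cat]
            edges += [left_lo, on_lo, on_hi, right_hi]
        # consecutive category ranges share their boundary exactly
        for a, b in zip(edges, edges[1:]):
            assert a < b or a == b
        assert edges[3] == edges[4] and edges[7] == edges[8]

    def test_widths(self):
        s = default_bin_scheme()
        assert s.on_width("R11") == pytest.approx(float(Fraction(1, 9)))
        assert s.off_width("R11") == pytest.approx(float(Fraction(4, 45)))
        # on/off widths are uneven: that is why the count model needs an offset
        assert s.on_width("R12") != pytest.approx(s.off_width("R12"))


class TestClassify:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.5, "on_R11"),
            (0.30, "off_R12"),
            (0.25, None),
            (1 / 3, "on_R12"),
            (2 / 3, "on_R21"),
            (0.75, None),
            (float(Fraction(5, 7)), "off_R21"),  # closed global maximum
        ],
    )
    def test_examples(self, r, expected):
        assert classify_ratio(r) == expected

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_domain_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_ratio(bad)

    def test_agrees_with_bruteforce_on_random_ratios(self):
        rng = np.random.default_rng(7)
        for r in rng.uniform(1e-6, 1 - 1e-6, size=1000):
            assert classify_ratio(float(r)) == brute_force_classify(float(r))


class TestCountBins:
    def test_counts_by_example(self, two_contributions):
        c = two_contributions[0]
        bc = count_bins(c, ratios=[0.5, 0.5, 0.33])
        assert bc.counts["on_R11"] == 2
        assert bc.counts["on_R12"] == 1
        assert sum(bc.counts.values()) == 3

    def test_empty_ratios_all_zero(self, two_contributions):
        bc = count_bins(two_contributions[0], ratios=[])
        assert all(v == 0 for v in bc.counts.values())
        assert bc.n_ratios == 0

    def test_uniform_draws_match_bruteforce_counts(self, two_contributions):
        rng = np.random.default_rng(123)
        ratios = rng.uniform(1e-9, 1 - 1e-9, size=1000)
        bc = count_bins(two_contributions[0], ratios=list(map(float, ratios)))
        expected = {label: 0 for label in BIN_LABELS}
        unbinned = 0
        for r in ratios:
            lab = brute_force_classify(float(r))
            if lab is None:
                unbinned += 1
            else:
                expected[lab] += 1
        assert bc.counts == expected
        assert bc.n_unbinned == unbinned


class TestTriples:
    def test_isochrony_maps_to_simplex_centre(self):
        (t,) = compute_triples(IOISequence((2.0, 2.0, 2.0), frozenset()))
        assert t == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_one_one_two_pattern(self):
        (t,) = compute_triples(IOISequence((2.0, 2.0, 4.0), frozenset()))
        assert t == (0.25, 0.25, 0.5)

    def test_two_one_one_pattern(self):
        (t,) = compute_triples(IOISequence((4.0, 2.0, 2.0), frozenset()))
        assert t == (0.5, 0.25, 0.25)

    def test_no_triple_spans_a_break(self):
        iois = IOISequence((2.0, 2.0, 2.0, 2.0), frozenset({1}))
        assert compute_triples(iois) == []
        iois2 = IOISequence((2.0, 2.0, 2.0, 2.0), frozenset({0}))
        assert len(compute_triples(iois2)) == 1


positive_iois = st.lists(
    st.floats(min_value=0.05, max_value=5.0, allow_nan=False), min_size=2, max_size=12
)


class TestInvariants:
    @given(positive_iois, st.integers(min_value=-3, max_value=3))
    @settings(max_examples=150, derandomize=True)
    def test_scale_invariance_power_of_two(self, ts, e):
        c = 2.0**e
        base = compute_ratios(IOISequence(tuple(ts), frozenset(), cap=10.0))
        scaled = compute_ratios(
            IOISequence(tuple(t * c for t in ts), frozenset(), cap=80.0)
        )
        assert scaled == base  # exact for power-of-two scalings

    @given(positive_iois, st.floats(min_value=0.1, max_value=3.0, allow_nan=False))
    @settings(max_examples=150, derandomize=True)
    def test_scale_invariance_general(self, ts, c):
        base = compute_ratios(IOISequence(tuple(ts), frozenset(), cap=10.0))
        scaled = compute_ratios(
            IOISequence(tuple(t * c for t in ts), frozenset(), cap=80.0)
        )
        assert scaled == pytest.approx(base, abs=1e-12)

    @given(positive_iois)
    @settings(max_examples=150, derandomize=True)
    def test_reversal_antisymmetry(self, ts):
        fwd = compute_ratios(IOISequence(tuple(ts), frozenset(), cap=10.0))
        rev = compute_ratios(IOISequence(tuple(reversed(ts)), frozenset(), cap=10.0))
        assert rev == pytest.approx([1 - r for r in reversed(fwd)], abs=1e-15)

    @given(
        st.floats(min_value=0.1, max_value=4.9, allow_nan=False),
        st.integers(min_value=2, max_value=20),
    )
    @settings(max_examples=100, derandomize=True)
    def test_isochronous_input_any_tempo(self, t, n):
        iois = IOISequence((t,) * n, frozenset())
        assert all(r == 0.5 for r in compute_ratios(iois))
        for trip in compute_triples(iois):
            assert trip == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-15)

    @given(positive_iois)
    @settings(max_examples=150, derandomize=True)
    def test_triples_normalised(self, ts):
        for trip in compute_triples(IOISequence(tuple(ts), frozenset(), cap=10.0)):
            assert sum(trip) == pytest.approx(1.0, abs=1e-12)
            assert all(0 < p < 1 for p in trip)
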