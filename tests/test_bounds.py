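import itertools
import math

import numpy as np
import pytest

from conftest import lambertw_bisect
from patterndict.bounds import (
    bound_report,
    lz78_log_upper_bound,
    lz78_lower_bound,
    lz78_upper_bound,
    max_phrase_construction_length,
    pda_score_range,
    typical_set_upper_bound,
)
from patterndict.dictionary import assign_codelengths, build_dictionary
from patterndict.lz78 import lz78_parse
from patterndict.pd_codec import pd_parse


class TestLambertW:
    def test_library_agrees_with_bisection_oracle(self):
        from scipy.special import lambertw

        for x in np.concatenate([np.linspace(0, 10, 41), 10.0 ** np.arange(1, 8)]):
            assert float(lambertw(x).real) == pytest.approx(
                lambertw_bisect(float(x)), abs=1e-10, rel=1e-10
            )


class TestLowerBound:
    @pytest.mark.parametrize("l,want", [(3, 2.0), (10, 4.0)])
    def test_triangular_lengths_closed_form(self, l, want):
        assert lz78_lower_bound(l) == pytest.approx(want)
        assert lz78_parse([0] * l).c == want  # constant sequence attains it

    def test_random_sequences_respect_bound(self):
        rng = np.random.default_rng(0)
        for l in (50, 100, 200):
            cs = [lz78_parse(rng.integers(0, 2, size=l)).c for _ in range(300)]
            assert min(cs) >= lz78_lower_bound(l) - 1e-9


class TestUpperBound:
    def test_small_binary_case_contains_exhaustive_max(self):
        max_c = max(lz78_parse(s).c for s in itertools.product((0, 1), repeat=6))
        ub = lz78_upper_bound(6, 2)
        assert max_c == 4
        assert ub >= max_c
        # W argument reduces to ln 2 here; check the bound via the oracle W
        assert ub == pytest.approx(6 * math.log(2) / lambertw_bisect(math.log(2)))

    def test_exact_at_construction_lengths(self):
        """At l_k the W inversion is exact: bound = l_k / (k - 1/alpha),
        and the packing construction count sum_j X^j is contained."""
        for x in (2, 3, 4):
            for k in range(1, 7):
                alpha = x - 1
                if k - 1 / alpha <= 0:
                    continue
                lk = max_phrase_construction_length(k, x)
                rep = bound_report(lk, x)
                assert rep.k == pytest.approx(k, abs=1e-8)
                assert rep.upper == pytest.approx(lk / (k - 1 / alpha))
                true_c = sum(x**j for j in range(1, k + 1))
                assert rep.upper >= true_c
                assert rep.upper / true_c <= k / (k - 1 / alpha) + 1e-9

    def test_increasing_in_length(self):
        vals = [lz78_upper_bound(l, 2) for l in range(10, 2000, 37)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_approaches_l_over_log_l(self):
        """The W bound converges (slowly, from above) to l/log_X(l)."""
        ratios = [
            lz78_upper_bound(10**e, 2) / (10**e / math.log2(10**e))
            for e in range(3, 8)
        ]
        assert all(b < a for a, b in zip(ratios, ratios[1:]))
        assert 1.0 < ratios[-1] < 1.5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lz78_upper_bound(2, 2)
        with pytest.raises(ValueError):
            lz78_upper_bound(100, 1)


class TestLogUpperBound:
    def test_closed_form_arithmetic_case(self):
        # X=2, l=2^16: eps = (4 + 4)/16 = 0.5 -> l / (0.5 * 16) = 8192
        assert lz78_log_upper_bound(2**16, 2) == pytest.approx(8192.0)

    def test_eps_decreases_with_length(self):
        bounds_over_l = [lz78_log_upper_bound(2**e, 2) / 2**e for e in range(10, 31, 2)]
        # bound/l = 1/((1-eps) log l): eps shrinking keeps this decreasing
        assert all(b < a for a, b in zip(bounds_over_l, bounds_over_l[1:]))

    def test_contains_random_phrase_counts(self):
        rng = np.random.default_rng(1)
        l = 2**12
        ub = lz78_log_upper_bound(l, 2)
        cs = [lz78_parse(rng.integers(0, 2, size=l)).c for _ in range(300)]
        assert max(cs) <= ub


class TestTypicalSetBound:
    def test_contains_fair_coin_phrase_counts(self):
        rng = np.random.default_rng(2)
        ub = typical_set_upper_bound(100, entropy_h=1.0, eps=0.1)
        cs = [lz78_parse(rng.integers(0, 2, size=100)).c for _ in range(1000)]
        assert max(cs) <= ub

    def test_increasing_in_entropy(self):
        vals = [typical_set_upper_bound(500, h, 0.1) for h in (0.5, 1.0, 1.5, 2.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matches_alphabet_bound_at_matching_growth_rate(self):
        """With 2^(h+eps) = X the packing count and the W-form alphabet bound
        describe the same construction, so they stay within a small factor."""
        for x in (2, 4):
            ts = typical_set_upper_bound(1000, entropy_h=math.log2(x) - 0.1, eps=0.1)
            ab = lz78_upper_bound(1000, x)
            assert 0.5 < ts / ab < 2.0

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            typical_set_upper_bound(100, 0.0, 0.1)
        with pytest.raises(ValueError):
            typical_set_upper_bound(100, 1.0, -0.1)


class TestScoreRange:
    def test_high_end_from_lower_bound(self):
        low, high = pda_score_range(10, 2, 3)
        assert high == pytest.approx(10 - 4)

    def test_range_admits_negative_scores(self):
        low, high = pda_score_range(6, 2, 5)
        assert low < 0

    def test_width_change_vanishes_with_dmax(self):
        widths = [np.diff(pda_score_range(200, 4, d))[0] for d in range(2, 30)]
        deltas = np.abs(np.diff(widths))
        assert all(b <= a + 1e-12 for a, b in zip(deltas, deltas[1:]))

    def test_contains_observed_phrase_count_differences(self):
        rng = np.random.default_rng(3)
        l, x, dmax = 100, 3, 6
        low, high = pda_score_range(l, x, dmax)
        for _ in range(200):
            train = rng.integers(0, x, size=300)
            pdict = assign_codelengths(build_dictionary(train, dmax))
            window = rng.integers(0, x, size=l)
            diff = pd_parse(pdict, window).c - lz78_parse(window).c
            assert low - 1e-9 <= diff <= high + 1e-9
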