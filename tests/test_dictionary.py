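import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import pattern
from patterndict.dictionary import (
    UnknownPatternError,
    PatternDictionary,
    assign_codelengths,
    build_dictionary,
    indexing_codelength,
    indexing_codelength_gap,
)


class TestBuild:
    def test_worked_example_level_sets(self, example_seq):
        d = build_dictionary(example_seq, 2)
        assert d.level_sizes == [4, 9]
        assert set(d.levels[2]) == {
            pattern(p) for p in ["AB", "BA", "AC", "CA", "AD", "DA", "BB", "CC", "DD"]
        }

    def test_worked_example_probabilities(self, table1_dict):
        assert table1_dict.levels[1][pattern("A")].prob == pytest.approx(11 / 25)
        assert table1_dict.levels[2][pattern("AB")].prob == pytest.approx(5 / 24)
        assert table1_dict.levels[3][pattern("ABA")].prob == pytest.approx(3 / 23)

    def test_single_symbol_sequence(self):
        d = build_dictionary([0, 0, 0, 0], 2)
        assert d.level_sizes == [1, 1]
        assert d.levels[1][(0,)].prob == 1.0
        assert d.levels[2][(0, 0)].prob == 1.0

    def test_window_counts_sum_exactly(self, example_seq):
        d = build_dictionary(example_seq, 3)
        for dep in (1, 2, 3):
            assert sum(e.count for e in d.levels[dep].values()) == 25 - dep + 1

    def test_prefix_and_suffix_closure(self, example_seq):
        d = build_dictionary(example_seq, 3)
        for dep in (2, 3):
            for p in d.levels[dep]:
                assert p[:-1] in d.levels[dep - 1]
                assert p[1:] in d.levels[dep - 1]

    @pytest.mark.parametrize("dmax,seq", [(5, [0, 1, 2]), (1, [])])
    def test_rejects_degenerate_input(self, dmax, seq):
        with pytest.raises(ValueError):
            build_dictionary(seq, dmax)


class TestCodelengths:
    def test_depth1_huffman_matches_worked_example(self, table1_dict):
        want = {"A": 1, "B": 2, "C": 3, "D": 3}
        for sym, cl in want.items():
            assert table1_dict.levels[1][pattern(sym)].codelength == cl

    def test_depth2_huffman_matches_worked_example(self, table1_dict):
        want = {"AB": 2, "BA": 3, "AC": 3, "CA": 3, "AD": 3, "DA": 3,
                "BB": 4, "CC": 5, "DD": 5}
        for sym, cl in want.items():
            assert table1_dict.levels[2][pattern(sym)].codelength == cl

    def test_uniform_probs_balanced_code(self):
        d = build_dictionary([0, 1, 2, 3] * 10 + [0], 1)
        assign_codelengths(d)
        assert all(e.codelength == 2 for e in d.levels[1].values())

    def test_kraft_inequality_every_level(self, table1_dict):
        for dep in (1, 2, 3):
            kraft = sum(2 ** -e.codelength for e in table1_dict.levels[dep].values())
            assert kraft <= 1 + 1e-9

    def test_huffman_beats_sfe_expected_length(self, example_seq):
        h = assign_codelengths(build_dictionary(example_seq, 3), "huffman")
        s = assign_codelengths(build_dictionary(example_seq, 3), "sfe")
        for dep in (1, 2, 3):
            eh = sum(e.prob * e.codelength for e in h.levels[dep].values())
            es = sum(e.prob * e.codelength for e in s.levels[dep].values())
            assert eh <= es + 1e-12

    def test_single_pattern_level_costs_one_bit(self):
        for method in ("huffman", "sfe"):
            d = assign_codelengths(build_dictionary([0, 0, 0, 0], 2), method)
            assert d.levels[2][(0, 0)].codelength == 1.0

    def test_unknown_method_rejected(self, example_seq):
        with pytest.raises(ValueError, match="method"):
            assign_codelengths(build_dictionary(example_seq, 2), "arithmetic")


class TestIndexing:
    def test_depth_index_plus_codeword(self, table1_dict):
        assert indexing_codelength(table1_dict, pattern("A")) == pytest.approx(
            1 + math.log2(3)
        )
        assert indexing_codelength(table1_dict, pattern("BB")) == pytest.approx(
            4 + math.log2(3)
        )

    def test_dmax_one_has_free_depth_index(self, example_seq):
        d = assign_codelengths(build_dictionary(example_seq, 1))
        assert indexing_codelength(d, pattern("A")) == 1.0

    def test_unknown_pattern_signal(self, table1_dict):
        with pytest.raises(UnknownPatternError):
            indexing_codelength(table1_dict, pattern("CB"))


class TestIndexingGap:
    def test_worked_example_gap(self):
        q = indexing_codelength_gap([4, 9])
        assert q["L_uni"] == pytest.approx(math.log2(13))
        assert q["L_multi"] == pytest.approx(1 + (2 + math.log2(9)) / 2)
        assert q["gap"] == pytest.approx(0.115, abs=5e-4)

    def test_equal_sizes_zero_gap(self):
        q = indexing_codelength_gap([7, 7, 7])
        assert q["gap"] == 0.0 == q["gap_lower_bound"] == q["gap_upper_bound"]

    @given(st.lists(st.integers(1, 5000), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_gap_nonnegative_and_bracketed(self, sizes):
        q = indexing_codelength_gap(sizes)
        assert q["gap"] >= -1e-12
        assert q["gap_lower_bound"] <= q["gap"] + 1e-9
        assert q["gap"] <= q["gap_upper_bound"] + 1e-9

    def test_rejects_empty_or_fractional_levels(self):
        with pytest.raises(ValueError):
            indexing_codelength_gap([])
        with pytest.raises(ValueError):
            indexing_codelength_gap([3, 0])


def test_json_roundtrip_is_canonical(table1_dict):
    text = table1_dict.to_json()
    again = PatternDictionary.from_json(text)
    assert again.to_json() == text
    assert again.levels[2][pattern("AB")].codelength == 2
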