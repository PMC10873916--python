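"""Scoring, caseness, stressor recoding, reliability and odds ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpsych import (ItemMeta, ItemResponseTable, build_node_matrix,
                      classify_probable_case, collapse_stressor_levels,
                      cronbach_alpha, filter_complete_cases,
                      merge_stressor_domains, odds_ratio, score_scale)
from netpsych.preprocess import summary_table


class TestCompleteCases:
    def test_no_missing_unchanged(self, toy_items):
        out = filter_complete_cases(toy_items, ["PHQ1", "PHQ2"])
        assert out.n == toy_items.n
        assert out.meta["n_removed"] == 0

    def test_row_with_missing_core_item_dropped(self, toy_items):
        v = toy_items.values.copy()
        v.loc[2, "PHQ1"] = np.nan
        t = ItemResponseTable(values=v, item_meta=toy_items.item_meta,
                              group=toy_items.group)
        out = filter_complete_cases(t, ["PHQ1"])
        assert out.n == 4
        assert out.meta["n_removed"] == 1
        assert len(out.group) == 4

    def test_all_missing_errors(self, toy_items):
        v = toy_items.values.copy()
        v["PHQ1"] = np.nan
        t = ItemResponseTable(values=v, item_meta=toy_items.item_meta)
        with pytest.raises(ValueError):
            filter_complete_cases(t, ["PHQ1"])


class TestScoringAndCaseness:
    @pytest.mark.parametrize("fill,expected", [(3, 27), (0, 0)])
    def test_phq9_extremes(self, fill, expected):
        values = pd.DataFrame({f"PHQ{i}": [fill] for i in range(1, 10)})
        meta = {f"PHQ{i}": ItemMeta("PHQ", 0, 3) for i in range(1, 10)}
        t = ItemResponseTable(values=values, item_meta=meta)
        assert score_scale(t, "PHQ").iloc[0] == expected

    def test_hand_summed_total(self, toy_items):
        assert list(score_scale(toy_items, "PHQ")) == [1, 2, 5, 5, 1]

    @pytest.mark.parametrize("total,expected", [(10, True), (9, False), (27, True)])
    def test_caseness_boundary_at_10(self, total, expected):
        assert bool(classify_probable_case(total)) is expected

    @given(st.integers(0, 27), st.integers(0, 27))
    def test_caseness_monotone_in_total(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_probable_case(lo) <= classify_probable_case(hi)


class TestStressorRecoding:
    @pytest.mark.parametrize("a,b,expected", [(2, 4, 3.0), (0, 0, 0.0), (1, 2, 1.5)])
    def test_merge_is_mean(self, a, b, expected):
        assert merge_stressor_domains(a, b) == expected

    @pytest.mark.parametrize("r,expected", [(0, 0), (1, 1), (3.5, 2), (0.5, 1),
                                            (1.5, 1), (2, 2), (4, 2)])
    def test_collapse_levels(self, r, expected):
        assert collapse_stressor_levels(r) == expected

    def test_collapse_rejects_negative(self):
        with pytest.raises(ValueError):
            collapse_stressor_levels(-0.1)

    def test_merge_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            merge_stressor_domains(5, 1)

    @given(st.sampled_from([0, 1, 2]))
    def test_merge_of_equal_collapsed_levels_is_idempotent(self, level):
        assert collapse_stressor_levels(merge_stressor_domains(level, level)) == level


class TestCronbachAlpha:
    def test_parallel_items_alpha_one(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([x, x, x])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 4, size=(50, 4)).astype(float)
        a1 = cronbach_alpha(X)
        X2 = X.copy()
        X2[:, 1] += 7
        assert cronbach_alpha(X2) == pytest.approx(a1)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20_000, 3))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_hand_computed_toy_matrix(self):
        X = np.array([[1, 2, 0], [2, 3, 1], [3, 3, 2], [0, 1, 0], [2, 2, 1]], float)
        # item variances 1.3, .7, .7; total variance 7.3 -> 1.5*(1 - 2.7/7.3)
        assert cronbach_alpha(X) == pytest.approx(0.9452054794520548)

    def test_zero_total_variance_errors(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((5, 3)))


class TestOddsRatio:
    def test_symmetric_table_or_one(self):
        assert odds_ratio([[10, 10], [10, 10]])["OR"] == pytest.approx(1.0)

    def test_cross_product(self):
        assert odds_ratio([[20, 10], [10, 20]])["OR"] == pytest.approx(4.0)

    def test_matches_textbook_wald_interval(self):
        out = odds_ratio([[12, 5], [7, 9]])
        assert out["OR"] == pytest.approx(3.085714285714286)
        assert out["CI95"][0] == pytest.approx(0.7335296468904554, rel=1e-9)
        assert out["CI95"][1] == pytest.approx(12.980569624451965, rel=1e-9)
        assert 0 < out["p"] < 1

    def test_zero_cell_haldane_flagged(self):
        out = odds_ratio([[5, 0], [3, 4]])
        assert out["haldane_corrected"]
        assert np.isfinite(out["OR"])


class TestNodeMatrix:
    def test_merge_then_collapse_composition(self, toy_items):
        m = build_node_matrix(toy_items, merge_plan=[("FIN", "WRK", "FW")])
        # row 2: (4 + 4)/2 = 4 -> collapsed 2
        assert m.values.loc[2, "FW"] == 2
        # row 1: (2 + 0)/2 = 1 -> collapsed 1
        assert m.values.loc[1, "FW"] == 1
        assert m.node_groups["FW"] == "STRESSOR"

    def test_no_merge_plan_collapses_individually(self, toy_items):
        m = build_node_matrix(toy_items)
        assert set(m.values["FIN"].unique()) <= {0, 1, 2}
        assert "WRK" in m.values.columns

    def test_canonical_ordering_and_passthrough(self, toy_items):
        m = build_node_matrix(toy_items, merge_plan=[("FIN", "WRK", "FW")])
        assert list(m.values.columns) == ["PHQ1", "PHQ2", "FW", "SSFm"]
        assert (m.values["SSFm"] == toy_items.values["SSFm"]).all()

    def test_unknown_merge_item_errors(self, toy_items):
        with pytest.raises(KeyError):
            build_node_matrix(toy_items, merge_plan=[("FIN", "nope", "FW")])

    def test_study_fixture_has_28_nodes(self):
        from netpsych import make_study_fixture
        t, _ = make_study_fixture(seed=0, group_sizes=(50, 50))
        m = build_node_matrix(t)
        assert m.values.shape[1] == 28

    def test_summary_table_schema(self, toy_items):
        out = summary_table(toy_items)
        assert set(out["scale"]) == {"PHQ"}
        assert {"n_cases", "pct_cases", "alpha", "OR"} <= set(out.columns)
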