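"""Verb engine: evaluation, selection, and the row/column verbs.

Where a verb duplicates standard dataframe behavior, pandas serves as
the independent oracle on the same data; the engine itself never calls
pandas.
"""

import numpy as np
import pandas as pd
import pytest

from shieldframe import ColumnVector, TabularFrame, generate_fixture, parse_tidy_expr
from shieldframe.frame import (GroupedFrame, ShapeError, TypeMismatchError,
                               UnknownColumnError)
from shieldframe.verbs import (ArgumentError, EvalContext, apply_arrange,
                               apply_bind_cols, apply_bind_rows,
                               apply_distinct, apply_filter, apply_group_by,
                               apply_mutate, apply_rename, apply_select,
                               apply_slice, apply_ungroup, compute_group_keys,
                               eval_case_when, eval_expr, eval_if_else,
                               resolve_selector, to_canonical_frame)

from conftest import CASE_WHEN_EXPR, FILTER_EXPR, MTCARS_COLUMNS


def _ctx(frame):
    return EvalContext.for_frame(frame)


def _expr(text):
    return parse_tidy_expr(text)


class TestEvalExpr:
    def test_identifier_returns_column_unchanged(self, mtcars):
        assert eval_expr(_ctx(mtcars), _expr("mpg")) == mtcars.columns["mpg"]

    def test_sqrt_of_constructed_vector(self, mtcars):
        out = eval_expr(_ctx(mtcars), _expr("sqrt(c(4, 9))"))
        assert out.to_list() == [2.0, 3.0]

    def test_comparison_yields_boolean(self):
        f = TabularFrame([("hp", ColumnVector([110, 245], "integer"))])
        out = eval_expr(_ctx(f), _expr("hp > 150"))
        assert out.dtype == "boolean"
        assert out.to_list() == [False, True]

    def test_missing_propagates_through_arithmetic(self):
        f = TabularFrame([("x", ColumnVector([1.0, None, 3.0], "numeric"))])
        out = eval_expr(_ctx(f), _expr("x * 2 + 1"))
        assert out.to_list() == [3.0, None, 7.0]

    def test_unknown_column_is_an_error(self, mtcars):
        with pytest.raises(UnknownColumnError):
            eval_expr(_ctx(mtcars), _expr("ghost + 1"))

    def test_string_plus_number_is_a_type_error(self):
        f = TabularFrame([("s", ColumnVector(["a"], "string"))])
        with pytest.raises(TypeMismatchError):
            eval_expr(_ctx(f), _expr("s + 1"))

    def test_scale_matches_zscore(self, mtcars):
        out = eval_expr(_ctx(mtcars), _expr("scale(mpg)"))
        x = np.array(mtcars.columns["mpg"].to_list())
        expected = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(out.values, expected)


class TestSelectors:
    def test_printed_five_name_selection_order(self, mtcars):
        node = _expr("list(mpg, cyl, hp, wt, gear)")
        out = apply_select(mtcars, node)
        assert out.column_order == ["mpg", "cyl", "hp", "wt", "gear"]
        assert out.n_rows == 32

    def test_everything_is_identity_selection(self, mtcars):
        assert resolve_selector(mtcars, _expr("everything()")) == MTCARS_COLUMNS

    def test_starts_with_scans_the_schema(self, mtcars):
        assert resolve_selector(mtcars, _expr('starts_with("c")')) == ["cyl", "carb"]

    def test_all_of_errors_but_any_of_skips(self, mtcars):
        with pytest.raises(UnknownColumnError):
            resolve_selector(mtcars, _expr('all_of(c("mpg", "ghost"))'))
        out = apply_select(mtcars, _expr('any_of(c("mpg", "ghost"))'))
        assert out.column_order == ["mpg"]

    def test_name_range_follows_column_order(self, mtcars):
        assert resolve_selector(mtcars, _expr("mpg:hp")) == ["mpg", "cyl", "disp", "hp"]

    def test_where_selects_by_dtype(self, mtcars):
        got = resolve_selector(mtcars, _expr("where(is.numeric)"))
        assert got == MTCARS_COLUMNS  # every fixture column is numeric-ish

    def test_duplicates_keep_first_occurrence(self, mtcars):
        out = apply_select(mtcars, _expr("list(cyl, everything())"))
        assert out.column_order[0] == "cyl"
        assert sorted(out.column_order) == sorted(MTCARS_COLUMNS)


class TestRenameMutate:
    def test_rename_changes_name_only(self, mtcars):
        out = apply_rename(mtcars, _expr("mpg2 = mpg"))
        assert "mpg2" in out.columns and "mpg" not in out.columns
        assert out.columns["mpg2"] == mtcars.columns["mpg"]
        assert out.column_order.index("mpg2") == 0

    def test_rename_collision_is_an_error(self, mtcars):
        with pytest.raises(Exception):
            apply_rename(mtcars, _expr("cyl = mpg"))

    def test_mutate_appends_new_column(self, mtcars):
        out = apply_mutate(mtcars, _expr("kpl = mpg * 0.425"))
        assert out.n_cols == 12 and out.column_order[-1] == "kpl"
        assert np.allclose(out.columns["kpl"].values,
                           mtcars.columns["mpg"].values * 0.425)

    def test_mutate_overwrites_in_place(self, mtcars):
        out = apply_mutate(mtcars, _expr("mpg = round(mpg)"))
        assert out.n_cols == mtcars.n_cols
        assert out.column_order == mtcars.column_order

    def test_grouped_mean_matches_pandas_transform(self, mtcars):
        grouped = apply_group_by(mtcars, ["cyl"])
        out = apply_mutate(grouped, _expr("m = mean(mpg)"))
        expected = (mtcars.to_pandas().groupby("cyl")["mpg"].transform("mean"))
        assert np.allclose(out.base.columns["m"].values, expected.to_numpy())

    def test_mutate_sees_earlier_assignments(self, mtcars):
        out = apply_mutate(mtcars, _expr("a = mpg * 2, b = a + 1"))
        assert np.allclose(out.columns["b"].values,
                           mtcars.columns["mpg"].values * 2 + 1)


class TestConditionals:
    def test_if_else_scalar_branches(self):
        cond = ColumnVector([True, False], "boolean")
        assert eval_if_else(cond, 1, 0).to_list() == [1, 0]

    def test_if_else_missing_condition_yields_missing(self):
        cond = ColumnVector([True, None, False], "boolean")
        assert eval_if_else(cond, 1, 0).to_list() == [1, None, 0]

    def test_if_else_incompatible_branch_dtypes(self):
        cond = ColumnVector([True], "boolean")
        with pytest.raises(TypeMismatchError):
            eval_if_else(cond, 1, "no")

    @pytest.mark.parametrize("mpg,category", [
        (14.3, 0), (17.5, 1), (22.0, 2), (30.4, 3),
        (15.0, 1), (20.0, 2), (25.0, 3),  # bin edges belong to the upper bin
    ])
    def test_four_bin_recode_assigns_printed_categories(self, mpg, category):
        f = TabularFrame([("mpg", ColumnVector([mpg], "numeric"))])
        out = eval_case_when(_ctx(f), _expr(CASE_WHEN_EXPR).items)
        assert out.to_list() == [category]

    def test_unmatched_row_falls_through_to_missing(self):
        f = TabularFrame([("x", ColumnVector([5.0], "numeric"))])
        out = eval_case_when(_ctx(f), [_expr("x > 10 ~ 1")])
        assert out.to_list() == [None]

    def test_first_matching_clause_wins(self):
        f = TabularFrame([("x", ColumnVector([7.0], "numeric"))])
        out = eval_case_when(_ctx(f), _expr("list(x > 1 ~ 10, x > 5 ~ 20)").items)
        assert out.to_list() == [10]

    def test_zero_clauses_is_an_error(self, mtcars):
        with pytest.raises(ArgumentError):
            eval_case_when(_ctx(mtcars), [])


class TestFilter:
    def test_conjunction_matches_brute_force_scan(self, mtcars):
        out = apply_filter(mtcars, _expr(FILTER_EXPR))
        df = mtcars.to_pandas()
        expected = df[(df.cyl > 6) & (df.hp > 150) & (df.wt < 3.5)]
        assert out.n_rows == len(expected)
        assert np.allclose(out.columns["mpg"].values, expected["mpg"].to_numpy())

    def test_always_true_is_identity(self, mtcars):
        assert apply_filter(mtcars, _expr("mpg > -1")) == mtcars

    def test_missing_predicate_drops_the_row(self):
        f = TabularFrame([("x", ColumnVector([1.0, None, 3.0], "numeric"))])
        out = apply_filter(f, _expr("x > 0"))
        assert out.columns["x"].to_list() == [1.0, 3.0]

    def test_grouping_metadata_preserved(self, mtcars):
        g = apply_group_by(mtcars, ["cyl"])
        out = apply_filter(g, _expr("mpg > 20"))
        assert isinstance(out, GroupedFrame) and out.group_cols == ("cyl",)

    @pytest.mark.parametrize("seed", range(12))
    def test_conjunction_equals_chained_single_filters(self, seed):
        f = generate_fixture(n_rows=40, seed=seed)
        joint = apply_filter(f, _expr(FILTER_EXPR))
        chained = apply_filter(
            apply_filter(apply_filter(f, _expr("cyl > 6")), _expr("hp > 150")),
            _expr("wt < 3.5"))
        assert joint == chained


class TestSliceArrange:
    def test_slice_basics(self, mtcars):
        assert apply_slice(mtcars, [1]).n_rows == 1
        assert apply_slice(mtcars, [40]).n_rows == 0
        two = apply_slice(mtcars, [2, 1])
        assert two.columns["mpg"].to_list() == [
            mtcars.columns["mpg"].to_list()[1], mtcars.columns["mpg"].to_list()[0]]

    def test_slice_negative_excludes(self, mtcars):
        out = apply_slice(mtcars, [-1, -2])
        assert out.n_rows == 30
        assert out.columns["mpg"].to_list() == mtcars.columns["mpg"].to_list()[2:]

    def test_slice_mixed_signs_rejected(self, mtcars):
        with pytest.raises(ArgumentError):
            apply_slice(mtcars, [1, -2])

    def test_arrange_desc_reverses_unique_keys(self, mtcars):
        up = apply_arrange(mtcars, _expr("mpg"))
        down = apply_arrange(mtcars, _expr("desc(mpg)"))
        assert up.columns["mpg"].to_list() == down.columns["mpg"].to_list()[::-1]

    def test_arrange_is_stable_on_ties(self):
        f = TabularFrame([("k", ColumnVector([1, 1, 0, 1], "integer")),
                          ("tag", ColumnVector(list("abcd"), "string"))])
        out = apply_arrange(f, _expr("k"))
        assert out.columns["tag"].to_list() == ["c", "a", "b", "d"]

    def test_arrange_missing_values_placed_last(self):
        f = TabularFrame([("x", ColumnVector([2.0, None, 1.0], "numeric"))])
        assert apply_arrange(f, _expr("x")).columns["x"].to_list() == [1.0, 2.0, None]
        assert apply_arrange(f, _expr("desc(x)")).columns["x"].to_list() == [2.0, 1.0, None]

    @pytest.mark.parametrize("seed", range(6))
    def test_two_key_sort_matches_pandas(self, seed):
        f = generate_fixture(n_rows=50, seed=seed)
        out = apply_arrange(f, _expr("cyl, desc(mpg)"))
        expected = f.to_pandas().sort_values(["cyl", "mpg"],
                                             ascending=[True, False],
                                             kind="stable", na_position="last")
        assert out.columns["mpg"].to_list() == expected["mpg"].tolist()

    def test_arrange_output_is_a_row_permutation(self, mtcars):
        out = apply_arrange(mtcars, _expr("wt, desc(hp)"))
        rows = lambda fr: sorted(map(tuple, zip(*[fr.columns[c].to_list()
                                                  for c in fr.column_order])))
        assert rows(out) == rows(mtcars)


class TestBind:
    @pytest.mark.parametrize("k", [0, 1, 13, 31, 32])
    def test_split_then_bind_rows_reconstructs(self, mtcars, k):
        top = apply_slice(mtcars, list(range(1, k + 1)))
        bottom = apply_slice(mtcars, list(range(k + 1, 33)))
        assert apply_bind_rows([top, bottom]) == mtcars

    def test_bind_rows_union_with_missing_fill(self):
        a = TabularFrame([("x", ColumnVector([1], "integer"))])
        b = TabularFrame([("y", ColumnVector([2.5], "numeric"))])
        out = apply_bind_rows([a, b])
        assert out.column_order == ["x", "y"]
        assert out.columns["x"].to_list() == [1, None]
        assert out.columns["y"].to_list() == [None, 2.5]

    def test_bind_rows_irreconcilable_dtypes(self):
        a = TabularFrame([("x", ColumnVector([1], "integer"))])
        b = TabularFrame([("x", ColumnVector(["s"], "string"))])
        with pytest.raises(TypeMismatchError):
            apply_bind_rows([a, b])

    def test_bind_cols_concatenates_and_suffixes(self, mtcars):
        left = apply_select(mtcars, _expr("list(mpg, cyl, hp, wt, gear)"))
        out = apply_bind_cols([left, mtcars])
        assert out.n_cols == 16
        assert "mpg__2" in out.column_order

    def test_bind_cols_unequal_rows_rejected(self, mtcars):
        with pytest.raises(ShapeError):
            apply_bind_cols([mtcars, apply_slice(mtcars, [1, 2])])


class TestGrouping:
    def test_group_ungroup_round_trip(self, mtcars):
        g = apply_group_by(mtcars, ["cyl", "gear"])
        assert g.group_cols == ("cyl", "gear")
        assert apply_ungroup(g) == mtcars

    def test_group_by_unknown_column(self, mtcars):
        with pytest.raises(UnknownColumnError):
            apply_group_by(mtcars, ["ghost"])

    def test_group_keys_match_brute_force_distinct(self, mtcars):
        g = apply_group_by(mtcars, ["cyl", "gear"])
        keys = compute_group_keys(g)
        expected = sorted({(c, r) for c, r in zip(
            mtcars.columns["cyl"].to_list(), mtcars.columns["gear"].to_list())})
        got = list(zip(keys.columns["cyl"].to_list(), keys.columns["gear"].to_list()))
        assert got == expected

    def test_group_keys_on_constant_column(self):
        f = TabularFrame([("k", ColumnVector([7, 7, 7], "integer"))])
        assert compute_group_keys(apply_group_by(f, ["k"])).n_rows == 1


class TestDistinct:
    def test_duplicated_rows_collapse(self):
        f = TabularFrame([("x", ColumnVector([1, 1], "integer"))])
        assert apply_distinct(f).n_rows == 1

    def test_idempotent(self, mtcars):
        once = apply_distinct(mtcars, ["cyl"], keep_all=True)
        assert apply_distinct(once, ["cyl"], keep_all=True) == once

    def test_count_matches_set_cardinality(self, mtcars):
        out = apply_distinct(mtcars, ["cyl"])
        assert out.n_rows == len(set(mtcars.columns["cyl"].to_list()))
        assert out.column_order == ["cyl"]


class TestCanonicalFrame:
    def test_frame_passes_through(self, mtcars):
        assert to_canonical_frame(mtcars) is mtcars

    def test_nameless_columns_get_v_names(self):
        out = to_canonical_frame([[1, 2], [3.5, 4.5]])
        assert out.column_order == ["V1", "V2"]
        assert [d for _, d in out.schema()] == ["integer", "numeric"]

    def test_ragged_input_rejected(self):
        with pytest.raises(ShapeError):
            to_canonical_frame([[1, 2], [3]])
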