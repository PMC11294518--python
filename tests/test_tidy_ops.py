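"""Clinical-table tidying operations."""

import pandas as pd
import pytest

from geotidy.model import AnnotationTable, OperationError, Pattern
from geotidy import tidy_ops


def table(**columns):
    n = len(next(iter(columns.values())))
    if "id" not in columns:
        columns = {"id": [f"GSM{i}" for i in range(1, n + 1)], **columns}
    return AnnotationTable(pd.DataFrame(columns, dtype=object), id_column="id")


class TestDropColumns:
    def test_drop_removes_only_listed_columns(self):
        t = table(a=["1", "2"], b=["3", "4"], last_update_date=["x", "y"])
        out = tidy_ops.drop_columns(t, ["last_update_date"])
        assert out.columns == ["id", "a", "b"]
        assert out.n_rows == 2

    def test_empty_list_is_identity(self):
        t = table(a=["1", "2"])
        assert tidy_ops.drop_columns(t, []).equals(t)

    def test_dropping_id_column_rejected(self):
        with pytest.raises(OperationError, match="id"):
            tidy_ops.drop_columns(table(a=["1"]), ["id"])

    def test_unknown_name_rejected(self):
        with pytest.raises(OperationError, match="nope"):
            tidy_ops.drop_columns(table(a=["1"]), ["nope"])

    def test_input_not_mutated(self):
        t = table(a=["1", "2"], b=["3", "4"])
        tidy_ops.drop_columns(t, ["b"])
        assert t.columns == ["id", "a", "b"]


class TestDropByPreset:
    def test_same_value_column_removed(self):
        t = table(tissue=["tissue: blood"] * 3, a=["1", "2", "2"])
        out, removed = tidy_ops.drop_by_preset(t, ["same_value"])
        assert removed == ["tissue"]
        assert out.columns == ["id", "a"]

    def test_web_address_column_removed(self):
        t = table(ftp=[f"ftp://x/{i}.CEL" for i in range(3)], a=["1", "1", "1"])
        out, removed = tidy_ops.drop_by_preset(t, ["web_addresses"])
        assert removed == ["ftp"]

    def test_missing_ignored_for_same_value_but_not_unique(self):
        # {"A","A",missing}: same_value drops it, all_unique keeps it
        t = table(c=["A", "A", None])
        _, removed = tidy_ops.drop_by_preset(t, ["same_value"])
        assert removed == ["c"]
        _, removed = tidy_ops.drop_by_preset(t, ["all_unique"])
        assert removed == []

    def test_all_missing_column_counts_as_same_value(self):
        t = table(c=[None, None], a=["1", "2"])
        _, removed = tidy_ops.drop_by_preset(t, ["same_value"])
        assert removed == ["c"]

    def test_dates_preset_accepts_the_dialect_set(self):
        t = table(
            iso=["2019-03-14", "2020-01-01"],
            mon=["Mar 14 2019", "Jan 5 2020"],
            slashed=["14/03/2019", "1/3/2020"],
            longform=["March 14, 2019", "July 2, 2021"],
            not_a_date=["Mar 14 2019", "soon"],
        )
        _, removed = tidy_ops.drop_by_preset(t, ["dates"])
        assert removed == ["iso", "mon", "slashed", "longform"]

    def test_presets_combine_disjunctively(self):
        t = table(const=["x", "x", "x"], uniq=["a", "b", "c"], keep=["a", "a", "b"])
        out, removed = tidy_ops.drop_by_preset(t, ["same_value", "all_unique"])
        assert set(removed) == {"const", "uniq"}
        assert "keep" in out.columns

    def test_zero_matches_is_valid(self):
        t = table(a=["x", "y", "y"])
        out, removed = tidy_ops.drop_by_preset(t, ["dates"])
        assert removed == [] and out.equals(t)

    def test_empty_preset_list_rejected(self):
        with pytest.raises(OperationError):
            tidy_ops.drop_by_preset(table(a=["1"]), [])


class TestShiftCells:
    def test_drifted_values_gathered_into_new_column(self):
        t = table(
            c1=["grade: G1", None, "grade: G3"],
            c2=[None, "grade: G2", None],
        )
        out = tidy_ops.shift_cells(t, ["c1", "c2"], Pattern("^grade:", "regex"), "grade")
        assert list(out.df["grade"]) == ["grade: G1", "grade: G2", "grade: G3"]
        # matched source cells blanked
        assert list(out.df["c1"]) == [None, None, None]
        assert list(out.df["c2"]) == [None, None, None]

    def test_no_match_gives_all_missing_and_untouched_sources(self):
        t = table(c1=["a", "b"], c2=["c", "d"])
        out = tidy_ops.shift_cells(t, ["c1", "c2"], Pattern("zzz"), "new")
        assert list(out.df["new"]) == [None, None]
        assert list(out.df["c1"]) == ["a", "b"]

    def test_first_matching_source_wins(self):
        t = table(c1=["grade: G1"], c2=["grade: G2"])
        out = tidy_ops.shift_cells(t, ["c1", "c2"], Pattern("grade"), "g")
        assert list(out.df["g"]) == ["grade: G1"]
        assert list(out.df["c2"]) == ["grade: G2"]  # later match stays put

    def test_empty_source_set_rejected(self):
        with pytest.raises(OperationError):
            tidy_ops.shift_cells(table(a=["1"]), [], Pattern("x"), "new")


class TestSplitKeyValue:
    def test_uniform_key_renames_column(self):
        t = table(c=["treatment:control", "treatment:drug"])
        out = tidy_ops.split_key_value(t, "c", Pattern(":"))
        assert "treatment" in out.columns and "c" not in out.columns
        assert list(out.df["treatment"]) == ["control", "drug"]

    def test_single_row_cell(self):
        t = table(c=["k:v"])
        out = tidy_ops.split_key_value(t, "c", Pattern(":"))
        assert list(out.df["k"]) == ["v"]

    def test_heterogeneous_keys_expand_wide(self):
        t = table(c=["sex: f", "age: 52", "sex: m"])
        out = tidy_ops.split_key_value(t, "c", Pattern(":"))
        assert "sex" in out.columns and "age" in out.columns
        assert list(out.df["sex"]) == ["f", None, "m"]
        assert list(out.df["age"]) == [None, "52", None]

    def test_absent_delimiter_is_warning_noop(self):
        t = table(c=["plain", "cells"])
        out = tidy_ops.split_key_value(t, "c", Pattern("="))
        assert out.equals(t)

    def test_whitespace_trimmed_around_key_and_value(self):
        t = table(c=["sex = female", "sex = male"])
        out = tidy_ops.split_key_value(t, "c", Pattern("="))
        assert list(out.df["sex"]) == ["female", "male"]


class TestSplitColumn:
    def test_worked_example_multi_value_cell(self):
        t = table(c=["female; 52; anastrozole"])
        out = tidy_ops.split_column(t, "c", Pattern("; "))
        assert list(out.df["c_1"]) == ["female"]
        assert list(out.df["c_2"]) == ["52"]
        assert list(out.df["c_3"]) == ["anastrozole"]

    def test_short_rows_padded_with_missing(self):
        t = table(c=["a;b", "c"])
        out = tidy_ops.split_column(t, "c", Pattern(";"))
        assert list(out.df["c_1"]) == ["a", "c"]
        assert list(out.df["c_2"]) == ["b", None]

    def test_absent_delimiter_keeps_values(self):
        t = table(c=["a", "b"])
        out = tidy_ops.split_column(t, "c", Pattern("|"))
        assert out.columns == ["id", "c_1"]
        assert list(out.df["c_1"]) == ["a", "b"]

    def test_max_parts_caps_the_split(self):
        t = table(c=["a;b;c"])
        out = tidy_ops.split_column(t, "c", Pattern(";"), max_parts=2)
        assert list(out.df["c_2"]) == ["b;c"]

    def test_new_columns_replace_original_in_place(self):
        t = table(before=["x"], c=["a;b"], after=["y"])
        out = tidy_ops.split_column(t, "c", Pattern(";"))
        assert out.columns == ["id", "before", "c_1", "c_2", "after"]


class TestRenameColumn:
    def test_only_the_name_changes(self):
        t = table(characteristics_ch1=["Relapse", "Non-relapse"])
        out = tidy_ops.rename_column(t, "characteristics_ch1", "relapse_status")
        assert out.columns == ["id", "relapse_status"]
        assert list(out.df["relapse_status"]) == ["Relapse", "Non-relapse"]

    def test_rename_to_itself_is_identity(self):
        t = table(a=["1"])
        assert tidy_ops.rename_column(t, "a", "a").equals(t)

    def test_collision_rejected(self):
        with pytest.raises(OperationError):
            tidy_ops.rename_column(table(a=["1"], b=["2"]), "a", "b")

    def test_unknown_old_rejected(self):
        with pytest.raises(OperationError):
            tidy_ops.rename_column(table(a=["1"]), "zz", "b")


class TestSubstitute:
    def test_whole_cell_literal(self):
        t = table(sex=["F", "F", "M"])
        out, n = tidy_ops.substitute(t, "sex", "F", "Female")
        assert n == 2
        assert list(out.df["sex"]) == ["Female", "Female", "M"]

    def test_harmonizing_relapse_vocabularies(self):
        t = table(relapse=["Yes", "No", "Relapse"])
        out, n = tidy_ops.substitute(t, "relapse", "Yes", "Relapse")
        assert n == 1
        assert list(out.df["relapse"]) == ["Relapse", "No", "Relapse"]

    def test_absent_match_changes_nothing(self):
        t = table(a=["x", "y"])
        out, n = tidy_ops.substitute(t, "a", "zzz", "w")
        assert n == 0 and out.equals(t)

    def test_regex_substring_mode(self):
        t = table(a=["grade: G1", "grade: G2"])
        out, n = tidy_ops.substitute(t, "a", r"^grade:\s*", "", "regex_substring")
        assert n == 2
        assert list(out.df["a"]) == ["G1", "G2"]

    def test_invalid_regex_rejected_before_mutation(self):
        t = table(a=["x"])
        with pytest.raises(OperationError):
            tidy_ops.substitute(t, "a", "[", "y", "regex_substring")

    def test_idempotent_when_replacement_differs_from_match(self):
        t = table(a=["F", "M", "F"])
        once, _ = tidy_ops.substitute(t, "a", "F", "Female")
        twice, n = tidy_ops.substitute(once, "a", "F", "Female")
        assert n == 0 and twice.equals(once)


class TestFilterRowsByValue:
    def test_excluding_males(self):
        t = table(sex=["male", "female", "male", "female", "female"])
        out, n = tidy_ops.filter_rows_by_value(t, "sex", ["male"])
        assert n == 2
        assert "male" not in list(out.df["sex"])
        assert out.n_rows + n == t.n_rows

    def test_absent_value_is_identity(self):
        t = table(a=["x", "y"])
        out, n = tidy_ops.filter_rows_by_value(t, "a", ["zzz"])
        assert n == 0 and out.equals(t)

    def test_survivor_order_and_columns_preserved(self):
        t = table(a=["1", "2", "3", "2", "4"], b=list("vwxyz"))
        out, n = tidy_ops.filter_rows_by_value(t, "a", ["2"])
        assert n == 2
        assert list(out.df["b"]) == ["v", "x", "z"]
        assert out.columns == t.columns
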