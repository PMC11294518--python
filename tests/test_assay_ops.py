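"""Assay summarization, filtering, and transposition."""

import numpy as np
import pandas as pd
import pytest

from geotidy import assay_ops
from geotidy.model import (
    FEATURES_BY_SAMPLES,
    SAMPLES_BY_FEATURES,
    AnnotationTable,
    AssayMatrix,
    IntegrityError,
    OperationError,
)


def features_table(mapping):
    return AnnotationTable(
        pd.DataFrame(
            {"ID": list(mapping), "GENE_SYMBOL": list(mapping.values())},
            dtype=object,
        ),
        id_column="ID",
    )


def matrix(values, n_samples=None, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i}" for i in range(1, values.shape[0] + 1)]
    samples = [f"GSM{j}" for j in range(1, values.shape[1] + 1)]
    return AssayMatrix("ID_REF", probes, samples, values)


class TestAttachFeatureIds:
    def test_full_mapping_drops_nothing(self):
        m = matrix(np.arange(12.0).reshape(6, 2))
        feats = features_table({f"P{i}": f"G{(i - 1) // 2 + 1}" for i in range(1, 7)})
        out = assay_ops.attach_feature_ids(m, feats, "GENE_SYMBOL")
        assert out.n_features == 6
        assert out.group_keys == ["G1", "G1", "G2", "G2", "G3", "G3"]

    def test_unmapped_probe_dropped_by_default(self):
        m = matrix(np.ones((6, 2)))
        feats = features_table({f"P{i}": f"G{i}" for i in range(1, 6)})  # P6 absent
        out = assay_ops.attach_feature_ids(m, feats, "GENE_SYMBOL")
        assert out.n_features == 5
        assert "P6" not in out.feature_ids

    def test_missing_group_key_counts_as_unmapped(self):
        m = matrix(np.ones((2, 2)))
        feats = features_table({"P1": "G1", "P2": None})
        out = assay_ops.attach_feature_ids(m, feats, "GENE_SYMBOL")
        assert out.feature_ids == ["P1"]

    def test_sentinel_policy_keeps_rows_under_own_id(self):
        m = matrix(np.ones((2, 2)))
        feats = features_table({"P1": "G1"})
        out = assay_ops.attach_feature_ids(
            m, feats, "GENE_SYMBOL", policy="keep_under_sentinel")
        assert out.n_features == 2
        assert out.group_keys == ["G1", "P2"]

    def test_empty_feature_table_drops_everything(self):
        m = matrix(np.ones((3, 2)))
        feats = features_table({})
        out = assay_ops.attach_feature_ids(m, feats, "GENE_SYMBOL")
        assert out.n_features == 0

    def test_unknown_target_column_rejected(self):
        m = matrix(np.ones((2, 2)))
        with pytest.raises(OperationError, match="nope"):
            assay_ops.attach_feature_ids(m, features_table({"P1": "G1"}), "nope")


def _keyed(values, keys):
    m = matrix(values)
    m.group_keys = list(keys)
    m.group_name = "GENE_SYMBOL"
    return m


class TestSummarize:
    def test_two_probe_gene_all_stats(self):
        m = _keyed([[2.0], [4.0]], ["G", "G"])
        assert assay_ops.summarize(m, "mean").values[0, 0] == 3.0
        assert assay_ops.summarize(m, "median").values[0, 0] == 3.0
        assert assay_ops.summarize(m, "min").values[0, 0] == 2.0
        assert assay_ops.summarize(m, "max").values[0, 0] == 4.0

    def test_singleton_groups_mean_is_identity(self):
        vals = np.arange(8.0).reshape(4, 2)
        m = _keyed(vals, ["A", "B", "C", "D"])
        out = assay_ops.summarize(m, "mean")
        assert np.array_equal(out.values, vals)
        assert out.feature_ids == ["A", "B", "C", "D"]
        assert out.feature_id_column == "GENE_SYMBOL"

    def test_missing_excluded_from_group_statistics(self):
        m = _keyed([[2.0], [np.nan]], ["G", "G"])
        assert assay_ops.summarize(m, "mean").values[0, 0] == 2.0

    def test_all_missing_group_sample_stays_missing(self):
        m = _keyed([[np.nan], [np.nan]], ["G", "G"])
        assert np.isnan(assay_ops.summarize(m, "median").values[0, 0])

    def test_keep_all_relabels_without_collapsing(self):
        vals = np.arange(6.0).reshape(3, 2)
        m = _keyed(vals, ["G1", "G1", "G2"])
        out = assay_ops.summarize(m, "keep_all")
        assert out.n_features == 3
        assert out.feature_ids == ["G1", "G1", "G2"]
        assert np.array_equal(out.values, vals)  # full value grid preserved

    def test_row_count_equals_distinct_group_keys(self):
        rng = np.random.default_rng(0)
        m = _keyed(rng.normal(size=(20, 3)), [f"G{i % 7}" for i in range(20)])
        out = assay_ops.summarize(m, "max")
        assert out.n_features == 7

    def test_order_statistics_bracket_mean_and_median(self):
        rng = np.random.default_rng(1)
        m = _keyed(rng.normal(size=(30, 4)), [f"G{i % 5}" for i in range(30)])
        lo = assay_ops.summarize(m, "min").values
        hi = assay_ops.summarize(m, "max").values
        for stat in ("mean", "median"):
            mid = assay_ops.summarize(m, stat).values
            assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12)

    def test_requires_group_keys(self):
        with pytest.raises(OperationError, match="attach_feature_ids"):
            assay_ops.summarize(matrix(np.ones((2, 2))), "mean")

    def test_unknown_stat_rejected(self):
        with pytest.raises(OperationError):
            assay_ops.summarize(_keyed([[1.0]], ["G"]), "variance")


class TestFilterAssayRows:
    def test_threshold_on_sample_column(self):
        vals = np.array([[float(i)] for i in range(10)])
        m = matrix(vals)
        out = assay_ops.filter_assay_rows(m, "GSM1", ">", 5.0)
        assert out.n_features == 4

    def test_threshold_below_minimum_keeps_all(self):
        m = matrix(np.arange(1.0, 7.0).reshape(3, 2))
        out = assay_ops.filter_assay_rows(m, "GSM1", ">", 0.0)
        assert out.n_features == 3

    def test_threshold_above_maximum_yields_valid_empty_matrix(self):
        m = matrix(np.arange(6.0).reshape(3, 2))
        out = assay_ops.filter_assay_rows(m, "GSM1", ">", 99.0)
        assert out.n_features == 0
        assert out.n_samples == 2

    def test_row_statistic_column(self):
        m = matrix([[1.0, 3.0], [10.0, 20.0]])
        out = assay_ops.filter_assay_rows(m, "row_mean", ">=", 10.0)
        assert out.feature_ids == ["P2"]

    def test_non_numeric_column_rejected(self):
        m = matrix(np.ones((2, 2)))
        with pytest.raises(OperationError, match="not numeric"):
            assay_ops.filter_assay_rows(m, "ID_REF", ">", 1.0)

    def test_commutes_with_summarize_for_singleton_groups(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(8, 3))
        m = _keyed(vals, [f"G{i}" for i in range(8)])
        a = assay_ops.filter_assay_rows(assay_ops.summarize(m, "mean"), "GSM2", ">", 0.0)
        b = assay_ops.summarize(
            assay_ops.filter_assay_rows(m, "GSM2", ">", 0.0), "mean")
        assert a.feature_ids == b.feature_ids
        assert np.array_equal(a.values, b.values)


class TestTranspose:
    def test_involution_is_cell_exact(self):
        m = matrix(np.arange(6.0).reshape(3, 2))
        back = assay_ops.transpose(assay_ops.transpose(m))
        assert back.orientation == FEATURES_BY_SAMPLES
        assert np.array_equal(back.to_frame().to_numpy(dtype=object),
                              m.to_frame().to_numpy(dtype=object))

    def test_cells_swap_indices(self):
        m = matrix(np.arange(6.0).reshape(3, 2))
        t = assay_ops.transpose(m)
        assert t.orientation == SAMPLES_BY_FEATURES
        a, b = m.to_frame(), t.to_frame()
        for i in range(3):
            for j in range(2):
                assert a.iloc[i, j + 1] == b.iloc[j, i + 1]
        assert t.shape == (2, 3)

    def test_duplicate_feature_ids_block_transpose(self):
        m = _keyed(np.ones((2, 2)), ["G", "G"])
        dup = assay_ops.summarize(m, "keep_all")
        with pytest.raises(IntegrityError, match="summarize"):
            assay_ops.transpose(dup)
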