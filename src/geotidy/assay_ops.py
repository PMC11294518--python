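"""Assay-matrix restructuring: probe-to-gene summarization, row filtering,
and transposition.

Microarray assay data typically arrive summarized per probe set, while many
analyses want one row per gene (or per cytoband, or whatever identifier the
platform table supplies). ``attach_feature_ids`` keys each assay row with a
group identifier from the platform annotations; ``summarize`` collapses each
group with a chosen statistic, or relabels without collapsing ("keep all").
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .model import (
    FEATURES_BY_SAMPLES,
    SAMPLES_BY_FEATURES,
    AnnotationTable,
    AssayMatrix,
    IntegrityError,
    OperationError,
    is_missing,
)

log = logging.getLogger("geotidy")

SUMMARY_STATS = ("mean", "median", "min", "max", "keep_all")
UNMAPPED_POLICIES = ("drop", "keep_under_sentinel")

_COMPARATORS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
    "=": np.equal,
    "==": np.equal,
}

#: Derived per-row statistics accepted by filter_assay_rows alongside
#: literal sample columns.
ROW_STATISTICS = {
    "row_mean": np.nanmean,
    "row_median": np.nanmedian,
    "row_min": np.nanmin,
    "row_max": np.nanmax,
}


def _record(recipe, op: str, params: dict, assay: AssayMatrix) -> None:
    if recipe is not None:
        recipe.add_event(
            op, "assay", params, rows=assay.n_features, columns=assay.n_samples
        )


def attach_feature_ids(
    assay: AssayMatrix,
    features: AnnotationTable,
    target_id_column: str,
    policy: str = "drop",
    *,
    recipe=None,
) -> AssayMatrix:
    """Key every assay row with a group identifier from the feature table.

    A row is unmapped when its feature id is absent from the feature table
    or its target cell is missing. Under the default ``drop`` policy
    unmapped rows are removed (count logged); ``keep_under_sentinel`` keeps
    them grouped under their own feature id.
    """
    if target_id_column not in features.columns:
        raise OperationError(
            f"unknown feature column {target_id_column!r}; "
            f"available: {features.columns}"
        )
    if policy not in UNMAPPED_POLICIES:
        raise OperationError(f"unknown policy {policy!r}; valid: {UNMAPPED_POLICIES}")
    mapping: dict[str, object] = {
        str(fid): val
        for fid, val in zip(features.df[features.id_column], features.df[target_id_column])
    }
    keep_rows: list[int] = []
    keys: list[str] = []
    n_unmapped = 0
    for i, fid in enumerate(assay.feature_ids):
        target = mapping.get(str(fid))
        if target is None or is_missing(target):
            n_unmapped += 1
            if policy == "keep_under_sentinel":
                keep_rows.append(i)
                keys.append(str(fid))
        else:
            keep_rows.append(i)
            keys.append(str(target))
    if n_unmapped:
        log.warning(
            "attach_feature_ids: %d unmapped feature(s) handled by policy %r",
            n_unmapped, policy,
        )
    out = AssayMatrix(
        feature_id_column=assay.feature_id_column,
        feature_ids=[assay.feature_ids[i] for i in keep_rows],
        sample_ids=list(assay.sample_ids),
        values=assay.values[keep_rows, :],
        orientation=assay.orientation,
        group_keys=keys,
        group_name=target_id_column,
    )
    _record(
        recipe, "attach_feature_ids",
        {"target_id_column": target_id_column, "policy": policy,
         "n_unmapped": n_unmapped},
        out,
    )
    return out


def summarize(assay: AssayMatrix, stat: str, *, recipe=None) -> AssayMatrix:
    """Collapse probe-level rows to one row per group key.

    For mean/median/min/max, each sample's value is that statistic over the
    group's non-missing values (an all-missing group-sample stays missing).
    ``keep_all`` relabels rows with their group key without collapsing, so
    duplicate identifiers are permitted afterwards. Output groups appear in
    order of first appearance.
    """
    if stat not in SUMMARY_STATS:
        raise OperationError(f"unknown statistic {stat!r}; valid: {SUMMARY_STATS}")
    if assay.group_keys is None:
        raise OperationError("assay rows carry no group keys; attach_feature_ids first")
    id_column = assay.group_name or assay.feature_id_column
    if stat == "keep_all":
        out = AssayMatrix(
            feature_id_column=id_column,
            feature_ids=list(assay.group_keys),
            sample_ids=list(assay.sample_ids),
            values=assay.values.copy(),
            orientation=assay.orientation,
        )
        _record(recipe, "summarize", {"stat": stat}, out)
        return out

    func = {
        "mean": np.nanmean, "median": np.nanmedian,
        "min": np.nanmin, "max": np.nanmax,
    }[stat]
    groups: list[str] = []
    members: dict[str, list[int]] = {}
    for i, key in enumerate(assay.group_keys):
        if key not in members:
            members[key] = []
            groups.append(key)
        members[key].append(i)
    grid = np.full((len(groups), assay.n_samples), np.nan)
    for g, key in enumerate(groups):
        block = assay.values[members[key], :]
        with np.errstate(invalid="ignore"):
            valid = ~np.all(np.isnan(block), axis=0)
            if valid.any():
                grid[g, valid] = func(block[:, valid], axis=0)
    out = AssayMatrix(
        feature_id_column=id_column,
        feature_ids=groups,
        sample_ids=list(assay.sample_ids),
        values=grid,
        orientation=assay.orientation,
    )
    _record(recipe, "summarize", {"stat": stat}, out)
    return out


def filter_assay_rows(
    assay: AssayMatrix,
    column: str,
    comparator: str,
    threshold: float,
    *,
    recipe=None,
) -> AssayMatrix:
    """Keep rows whose value in *column* satisfies ``value <cmp> threshold``.

    *column* is either a sample id or one of the derived row statistics
    (``row_mean``, ``row_median``, ``row_min``, ``row_max``). Missing values
    never satisfy the predicate. A zero-row result is a valid empty matrix.
    """
    if comparator not in _COMPARATORS:
        raise OperationError(
            f"unknown comparator {comparator!r}; valid: {sorted(_COMPARATORS)}"
        )
    if column in ROW_STATISTICS:
        with np.errstate(invalid="ignore"):
            all_nan = np.all(np.isnan(assay.values), axis=1)
            col = np.full(assay.n_features, np.nan)
            if (~all_nan).any():
                col[~all_nan] = ROW_STATISTICS[column](
                    assay.values[~all_nan, :], axis=1
                )
    elif column in assay.sample_ids:
        col = assay.values[:, assay.sample_ids.index(column)]
    elif column == assay.feature_id_column:
        raise OperationError(
            f"column {column!r} is not numeric; name a sample column or a "
            f"row statistic {sorted(ROW_STATISTICS)}"
        )
    else:
        raise OperationError(
            f"unknown column {column!r}; name a sample id or one of "
            f"{sorted(ROW_STATISTICS)}"
        )
    with np.errstate(invalid="ignore"):
        mask = _COMPARATORS[comparator](col, float(threshold))
    mask = np.asarray(mask, dtype=bool) & ~np.isnan(col)
    keep = np.nonzero(mask)[0]
    out = AssayMatrix(
        feature_id_column=assay.feature_id_column,
        feature_ids=[assay.feature_ids[i] for i in keep],
        sample_ids=list(assay.sample_ids),
        values=assay.values[keep, :],
        orientation=assay.orientation,
        group_keys=None if assay.group_keys is None
        else [assay.group_keys[i] for i in keep],
        group_name=assay.group_name,
    )
    _record(
        recipe, "filter_assay_rows",
        {"column": column, "comparator": comparator, "threshold": float(threshold),
         "n_removed": assay.n_features - len(keep)},
        out,
    )
    return out


def transpose(assay: AssayMatrix, *, recipe=None) -> AssayMatrix:
    """Flip between features-by-samples and samples-by-features.

    Transposing twice is the identity, cell for cell. Flipping to
    samples-by-features requires unique feature ids, since they become
    column headers — summarize a ``keep_all`` matrix first.
    """
    new_orientation = (
        SAMPLES_BY_FEATURES
        if assay.orientation == FEATURES_BY_SAMPLES
        else FEATURES_BY_SAMPLES
    )
    if new_orientation == SAMPLES_BY_FEATURES:
        if len(set(assay.feature_ids)) != len(assay.feature_ids):
            raise IntegrityError(
                "duplicate feature ids cannot become column headers; "
                "summarize (collapse) the assay before transposing"
            )
    out = AssayMatrix(
        feature_id_column=assay.feature_id_column,
        feature_ids=list(assay.feature_ids),
        sample_ids=list(assay.sample_ids),
        values=assay.values.copy(),
        orientation=new_orientation,
        group_keys=None if assay.group_keys is None else list(assay.group_keys),
        group_name=assay.group_name,
    )
    _record(recipe, "transpose", {}, out)
    return out
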