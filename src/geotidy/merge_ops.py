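"""Joining tidied clinical annotations with transposed assay data.

The merged table has one row per sample, clinical columns first, then one
column per assay feature. Join semantics follow the usual relational kinds:
inner (samples present on both sides), left (all clinical samples), right
(all assay samples), full (the union). Row order is deterministic —
left-side order first, then unmatched right-side keys in their original
order — so replayed exports are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    SAMPLES_BY_FEATURES,
    AnnotationTable,
    AssayMatrix,
    IntegrityError,
    OperationError,
)

JOIN_KINDS = ("inner", "left", "right", "full")

CLINICAL_SUFFIX = ".clin"
ASSAY_SUFFIX = ".assay"


@dataclass(frozen=True)
class JoinSpec:
    """Join kind plus the sample-accession key column name.

    ``key=None`` uses the clinical table's id column.
    """

    kind: str = "inner"
    key: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in JOIN_KINDS:
            raise OperationError(f"unknown join kind {self.kind!r}; valid: {JOIN_KINDS}")


def merge_tables(
    clinical: AnnotationTable,
    assay: AssayMatrix,
    spec: JoinSpec = JoinSpec(),
    *,
    recipe=None,
) -> AnnotationTable:
    """Join a clinical table with a samples-by-features assay matrix.

    Cell values pass through exactly (no coercion); unmatched rows are
    filled with missing; colliding column names get origin suffixes.
    """
    if assay.orientation != SAMPLES_BY_FEATURES:
        raise OperationError(
            "assay must be in samples-by-features orientation; transpose it first"
        )
    if spec.key is not None and spec.key not in clinical.columns:
        raise OperationError(f"key column {spec.key!r} not in clinical table")
    key_col = spec.key if spec.key is not None else clinical.id_column
    clin_keys = [str(v) for v in clinical.df[key_col]]
    if len(set(clin_keys)) != len(clin_keys):
        raise IntegrityError("duplicate keys on the clinical side")
    assay_keys = [str(s) for s in assay.sample_ids]
    if len(set(assay_keys)) != len(assay_keys):
        raise IntegrityError("duplicate keys on the assay side")
    if len(set(assay.feature_ids)) != len(assay.feature_ids):
        raise IntegrityError("duplicate feature ids; summarize the assay first")

    clin_set, assay_set = set(clin_keys), set(assay_keys)
    if spec.kind == "inner":
        keys = [k for k in clin_keys if k in assay_set]
    elif spec.kind == "left":
        keys = list(clin_keys)
    elif spec.kind == "right":
        keys = [k for k in clin_keys if k in assay_set] + [
            k for k in assay_keys if k not in clin_set
        ]
    else:  # full
        keys = list(clin_keys) + [k for k in assay_keys if k not in clin_set]

    # resolve column-name collisions by origin suffix
    feature_names = [str(f) for f in assay.feature_ids]
    collisions = set(clinical.columns) & set(feature_names)
    clin_names = {
        c: (c + CLINICAL_SUFFIX if c in collisions and c != key_col else c)
        for c in clinical.columns
    }
    feat_names = [
        f + ASSAY_SUFFIX if f in collisions else f for f in feature_names
    ]

    clin_index = {k: i for i, k in enumerate(clin_keys)}
    assay_index = {k: i for i, k in enumerate(assay_keys)}
    data: dict[str, list[object]] = {}
    for col in clinical.columns:
        out_name = clin_names[col]
        if col == key_col:
            data[out_name] = list(keys)
            continue
        data[out_name] = [
            clinical.df.at[clin_index[k], col] if k in clin_index else None
            for k in keys
        ]
    for j, name in enumerate(feat_names):
        column: list[object] = []
        for k in keys:
            if k in assay_index:
                v = assay.values[j, assay_index[k]]
                column.append(None if np.isnan(v) else v)
            else:
                column.append(None)
        data[name] = column
    df = pd.DataFrame(data, dtype=object)
    merged = AnnotationTable(df, id_column=clin_names[key_col])
    if recipe is not None:
        recipe.add_event(
            "merge_tables", "merged",
            {"kind": spec.kind, "key": spec.key},
            rows=merged.n_rows, columns=len(merged.columns),
        )
    return merged
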