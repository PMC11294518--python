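"""Table export in five formats (CSV, TSV, JSON, Excel, BRB-ArrayTools) and
text-format reading for round-trips.

Text exports are deterministic: fixed column order, minimal RFC-4180-style
quoting, ``\\n`` line endings — an identical table always produces
byte-identical output, which the provenance replay machinery relies on.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import IO

import numpy as np

from .model import (
    DEFAULT_MISSING_TOKENS,
    AnnotationTable,
    AssayMatrix,
    OperationError,
    ParseError,
)

FORMATS = ("csv", "tsv", "json", "xlsx", "brb")
READABLE_FORMATS = ("csv", "tsv", "json")


def _cell_text(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _maybe_number(value: object):
    """JSON coercion: numeric-looking cells become numbers, all else strings."""
    if isinstance(value, (int, float)):
        return value
    text = str(value)
    try:
        f = float(text)
    except ValueError:
        return text
    if f == int(f) and "." not in text and "e" not in text.lower():
        return int(f)
    return f


def _as_frame(table: AnnotationTable | AssayMatrix):
    if isinstance(table, AssayMatrix):
        return table.to_frame()
    return table.df


def write_table(
    table: AnnotationTable | AssayMatrix,
    format: str,
    path: str | Path,
    *,
    sheet_name: str = "data",
    clinical: AnnotationTable | None = None,
    recipe=None,
    table_role: str = "clinical",
) -> dict[str, int]:
    """Write *table* to *path* in one of the five supported formats.

    Returns ``{"rows": ..., "columns": ...}`` for the written table. For
    ``brb``, *table* must be an assay matrix (features x arrays) and *path*
    is a stem: ``<stem>_expression.txt`` is always written and, when a
    *clinical* table is supplied, ``<stem>_covariates.txt`` with one row per
    array in expression-column order.
    """
    if format not in FORMATS:
        raise OperationError(f"unknown format {format!r}; supported: {FORMATS}")
    path = Path(path)
    if format == "brb":
        summary = _write_brb(table, path, clinical)
    else:
        df = _as_frame(table)
        if format in ("csv", "tsv"):
            _write_delimited(df, path, "," if format == "csv" else "\t")
        elif format == "json":
            _write_json(df, path)
        else:
            _write_xlsx(df, path, sheet_name)
        summary = {"rows": len(df), "columns": len(df.columns)}
    if recipe is not None:
        recipe.add_event(
            "write_table", table_role,
            {"format": format, "filename": path.name},
            rows=summary["rows"], columns=summary["columns"],
        )
    return summary


def _write_delimited(df, path: Path, delimiter: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(
            fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL, lineterminator="\n"
        )
        writer.writerow(list(df.columns))
        for _, row in df.iterrows():
            writer.writerow([_cell_text(v) for v in row])


def _write_json(df, path: Path) -> None:
    records = []
    for _, row in df.iterrows():
        records.append(
            {
                col: (None if v is None or (isinstance(v, float) and np.isnan(v))
                      else _maybe_number(v))
                for col, v in zip(df.columns, row)
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def _write_xlsx(df, path: Path, sheet_name: str) -> None:
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = sheet_name
    ws.append(list(df.columns))
    for _, row in df.iterrows():
        ws.append([None if v is None else v for v in row])
    wb.save(path)


def _write_brb(
    table: AnnotationTable | AssayMatrix, stem: Path, clinical: AnnotationTable | None
) -> dict[str, int]:
    """BRB-ArrayTools paired-file layout.

    Expression file: tab-delimited, first column the feature identifier, one
    column per array named by GSM accession. Covariate file: tab-delimited,
    header row of covariate names, one row per array in the same order as
    the expression columns.
    """
    if not isinstance(table, AssayMatrix):
        raise OperationError(
            "brb export needs an assay matrix (features x arrays); "
            "the table lacks a sample/feature identifier pairing"
        )
    expr_path = stem.parent / (stem.name + "_expression.txt")
    header = [table.feature_id_column] + [str(s) for s in table.sample_ids]
    with open(expr_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for fid, row in zip(table.feature_ids, table.values):
            cells = [str(fid)] + [
                "" if np.isnan(v) else repr(float(v)) for v in row
            ]
            fh.write("\t".join(cells) + "\n")
    if clinical is not None:
        cov_path = stem.parent / (stem.name + "_covariates.txt")
        index = {
            str(v): i for i, v in enumerate(clinical.df[clinical.id_column])
        }
        missing = [s for s in table.sample_ids if str(s) not in index]
        if missing:
            raise OperationError(
                f"arrays absent from the covariate (clinical) table: {missing}"
            )
        with open(cov_path, "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(clinical.columns) + "\n")
            for s in table.sample_ids:
                row = clinical.df.iloc[index[str(s)]]
                fh.write("\t".join(_cell_text(v) for v in row) + "\n")
    return {"rows": table.n_features, "columns": table.n_samples}


def read_table(
    path: str | Path,
    format: str,
    id_column: str | None = None,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
) -> AnnotationTable:
    """Read a csv/tsv/json file back into an :class:`AnnotationTable`.

    Columns keep file order; missing tokens map to missing. JSON arrays with
    heterogeneous keys yield the column union (keys in first-appearance
    order), missing where a record lacks a key. ``id_column`` defaults to
    the first column.
    """
    if format not in READABLE_FORMATS:
        raise OperationError(f"unreadable format {format!r}; supported: {READABLE_FORMATS}")
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"empty file: {path}")
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            records = json.load(fh)
        if not isinstance(records, list) or not records:
            raise ParseError("expected a non-empty JSON array of row objects")
        columns: list[str] = []
        for rec in records:
            for k in rec:
                if k not in columns:
                    columns.append(k)
        rows = [[rec.get(c) for c in columns] for rec in records]
        rows = [
            [None if v is None else str(v) for v in row] for row in rows
        ]
    else:
        delimiter = "," if format == "csv" else "\t"
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter=delimiter)
            try:
                columns = next(reader)
            except StopIteration:
                raise ParseError(f"empty file: {path}") from None
            rows = []
            for lineno, row in enumerate(reader, start=2):
                if len(row) != len(columns):
                    raise ParseError(
                        f"ragged row at line {lineno}: expected "
                        f"{len(columns)} fields, got {len(row)}"
                    )
                rows.append(row)
    return AnnotationTable.from_rows(
        columns, rows, id_column or columns[0], missing_tokens
    )
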