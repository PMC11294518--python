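"""Column- and row-level tidying operations for annotation tables.

These are the eight "clinical data" tasks — selecting informative columns,
shifting drifted cells back into a single variable, splitting key-value
pairs, splitting delimited cells, renaming, substituting values, and
filtering samples — implemented as pure table-to-table transformations.
They apply unchanged to platform (feature) annotation tables, which suffer
the same pathologies.

Every operation accepts an optional ``recipe``; when given, exactly one
provenance event is appended (see :mod:`geotidy.recipe`).
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .model import AnnotationTable, OperationError, Pattern, as_pattern, is_missing

# ---------------------------------------------------------------------------
# Column presets
# ---------------------------------------------------------------------------

#: Date dialects accepted by the ``dates`` preset. The list is data: extend it
#: to accept more submitter conventions.
DATE_DIALECTS: list[str] = [
    r"\d{4}-\d{2}-\d{2}",                                   # ISO 8601
    r"[A-Z][a-z]{2} \d{1,2} \d{4}",                          # Mon DD YYYY
    r"\d{1,2}/\d{1,2}/\d{4}",                                # DD/MM/YYYY or MM/DD/YYYY
    r"[A-Z][a-z]{2,8} \d{1,2}, \d{4}",                       # Month DD, YYYY
]
_DATE_RE = re.compile("^(" + "|".join(DATE_DIALECTS) + ")$")

_URL_PREFIXES = ("http://", "https://", "ftp://")

PRESET_NAMES = ("same_value", "all_unique", "dates", "web_addresses")


def _nonmissing(values: Iterable[object]) -> list[str]:
    return [str(v) for v in values if not is_missing(v)]


def is_same_value(values: Iterable[object]) -> bool:
    """All non-missing cells equal; an entirely missing column qualifies."""
    return len(set(_nonmissing(values))) <= 1


def is_all_unique(values: Iterable[object]) -> bool:
    vals = _nonmissing(values)
    return len(vals) > 0 and len(set(vals)) == len(vals)


def is_dates(values: Iterable[object]) -> bool:
    vals = _nonmissing(values)
    return len(vals) > 0 and all(_DATE_RE.match(v) for v in vals)


def is_web_addresses(values: Iterable[object]) -> bool:
    vals = _nonmissing(values)
    return len(vals) > 0 and all(v.startswith(_URL_PREFIXES) for v in vals)


PRESETS = {
    "same_value": is_same_value,
    "all_unique": is_all_unique,
    "dates": is_dates,
    "web_addresses": is_web_addresses,
}


def _record(recipe, op: str, table_role: str, params: dict, table: AnnotationTable) -> None:
    if recipe is not None:
        recipe.add_event(op, table_role, params, rows=table.n_rows, columns=len(table.columns))


def _pattern_params(pattern: Pattern) -> dict:
    return {"text": pattern.text, "mode": pattern.mode}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def drop_columns(
    table: AnnotationTable,
    names: Sequence[str],
    *,
    recipe=None,
    table_role: str = "clinical",
) -> AnnotationTable:
    """Remove the listed columns; rows are untouched."""
    unknown = [n for n in names if n not in table.columns]
    if unknown:
        raise OperationError(f"unknown column(s): {unknown}")
    if table.id_column in names:
        raise OperationError(f"cannot drop id column {table.id_column!r}")
    out = table.copy()
    out.df = out.df.drop(columns=list(names))
    out.validate()
    _record(recipe, "drop_columns", table_role, {"names": list(names)}, out)
    return out


def drop_by_preset(
    table: AnnotationTable,
    presets: Sequence[str],
    *,
    recipe=None,
    table_role: str = "clinical",
) -> tuple[AnnotationTable, list[str]]:
    """Drop every non-id column matching ANY selected preset predicate.

    Returns the new table and the list of removed column names (possibly
    empty — zero matches is a valid outcome).
    """
    if not presets:
        raise OperationError("at least one preset is required")
    unknown = [p for p in presets if p not in PRESETS]
    if unknown:
        raise OperationError(f"unknown preset(s): {unknown}; valid: {PRESET_NAMES}")
    removed = [
        col
        for col in table.columns
        if col != table.id_column
        and any(PRESETS[p](table.df[col]) for p in presets)
    ]
    out = table.copy()
    out.df = out.df.drop(columns=removed)
    _record(
        recipe, "drop_by_preset", table_role,
        {"presets": list(presets), "removed": removed}, out,
    )
    return out, removed


def _matches(cell: object, pattern: Pattern) -> bool:
    if is_missing(cell):
        return False
    text = str(cell)
    if pattern.mode == "regex":
        return re.search(pattern.text, text) is not None
    return pattern.text in text


def shift_cells(
    table: AnnotationTable,
    source_columns: Sequence[str],
    pattern: Pattern | str,
    new_column: str,
    *,
    recipe=None,
    table_role: str = "clinical",
) -> AnnotationTable:
    """Gather drifted values into one new column.

    Per row, the first source cell (in the given column order) matching the
    pattern is moved: copied into ``new_column`` and blanked at the source.
    Rows with no match get missing. Moving rather than copying preserves the
    multiset of non-missing values across sources plus target.
    """
    if not source_columns:
        raise OperationError("shift_cells requires at least one source column")
    unknown = [c for c in source_columns if c not in table.columns]
    if unknown:
        raise OperationError(f"unknown source column(s): {unknown}")
    if new_column in table.columns:
        raise OperationError(f"column {new_column!r} already exists")
    pattern = as_pattern(pattern)
    out = table.copy()
    moved: list[object] = []
    for i in range(out.n_rows):
        value = None
        for col in source_columns:
            cell = out.df.at[i, col]
            if _matches(cell, pattern):
                value = cell
                out.df.at[i, col] = None
                break
        moved.append(value)
    out.df[new_column] = moved
    out.validate()
    _record(
        recipe, "shift_cells", table_role,
        {
            "source_columns": list(source_columns),
            "pattern": _pattern_params(pattern),
            "new_column": new_column,
        },
        out,
    )
    return out


def _split_once(text: str, pattern: Pattern) -> tuple[str, str] | None:
    if pattern.mode == "regex":
        m = re.search(pattern.text, text)
        if m is None:
            return None
        return text[: m.start()], text[m.end():]
    idx = text.find(pattern.text)
    if idx < 0:
        return None
    return text[:idx], text[idx + len(pattern.text):]


def split_key_value(
    table: AnnotationTable,
    column: str,
    pattern: Pattern | str,
    *,
    recipe=None,
    table_role: str = "clinical",
) -> AnnotationTable:
    """Promote key-value cells ("treatment:control") into named columns.

    When every non-missing cell splits on the delimiter and all trimmed keys
    agree, the column is renamed to that key and cells keep only the value.
    Heterogeneous keys expand the column in place into one column per
    distinct key (missing where a row lacks that key); rows whose cell has
    no delimiter keep their value under the original column name. A
    delimiter absent from every cell is a warning no-op.
    """
    if column not in table.columns:
        raise OperationError(f"unknown column {column!r}")
    pattern = as_pattern(pattern)
    cells = list(table.df[column])
    splits: list[tuple[str, str] | None] = [
        None if is_missing(c) else _split_once(str(c), pattern) for c in cells
    ]
    if not any(s is not None for s in splits):
        out = table.copy()
        _record(
            recipe, "split_key_value", table_role,
            {"column": column, "pattern": _pattern_params(pattern),
             "warning": "delimiter not found in any cell"},
            out,
        )
        return out

    keys = [s[0].strip() for s in splits if s is not None]
    n_nonmissing = sum(1 for c in cells if not is_missing(c))
    uniform = len(set(keys)) == 1 and len(keys) == n_nonmissing
    out = table.copy()
    col_idx = out.columns.index(column)
    if uniform:
        key = keys[0]
        if key in out.columns and key != column:
            raise OperationError(f"key {key!r} collides with an existing column")
        values = [
            None if s is None else (s[1].strip() or None) for s in splits
        ]
        out.df[column] = values
        out.df = out.df.rename(columns={column: key})
        out.validate()
        _record(
            recipe, "split_key_value", table_role,
            {"column": column, "pattern": _pattern_params(pattern),
             "heterogeneous": False},
            out,
        )
        return out

    # heterogeneous keys: wide expansion, one column per distinct key
    distinct: list[str] = []
    for k in keys:
        if k not in distinct:
            distinct.append(k)
    new_cols: dict[str, list[object]] = {k: [None] * len(cells) for k in distinct}
    keyless: list[object] = [None] * len(cells)
    any_keyless = False
    for i, (cell, s) in enumerate(zip(cells, splits)):
        if is_missing(cell):
            continue
        if s is None:
            keyless[i] = cell
            any_keyless = True
        else:
            new_cols[s[0].strip()][i] = s[1].strip() or None
    ordered: list[tuple[str, list[object]]] = []
    if any_keyless:
        ordered.append((column, keyless))
    ordered.extend(new_cols.items())
    for name, _ in ordered:
        if name != column and name in out.columns:
            raise OperationError(f"key {name!r} collides with an existing column")
    before = out.columns[:col_idx]
    after = out.columns[col_idx + 1:]
    out.df = out.df.drop(columns=[column])
    for name, vals in ordered:
        out.df[name] = vals
    out.df = out.df[list(before) + [n for n, _ in ordered] + list(after)]
    out.validate()
    _record(
        recipe, "split_key_value", table_role,
        {"column": column, "pattern": _pattern_params(pattern),
         "heterogeneous": True},
        out,
    )
    return out


def split_column(
    table: AnnotationTable,
    column: str,
    pattern: Pattern | str,
    max_parts: int | None = None,
    *,
    recipe=None,
    table_role: str = "clinical",
) -> AnnotationTable:
    """Split multi-value cells on a delimiter into ``column_1..column_k``.

    ``k`` is the maximum part count over rows (capped by ``max_parts``);
    shorter rows are padded with missing; parts are whitespace-trimmed. The
    new columns replace the original in place. A delimiter absent everywhere
    yields a single ``column_1`` with values unchanged.
    """
    if column not in table.columns:
        raise OperationError(f"unknown column {column!r}")
    if max_parts is not None and max_parts < 1:
        raise OperationError("max_parts must be >= 1")
    pattern = as_pattern(pattern)
    maxsplit = 0 if max_parts is None else max_parts - 1
    parts_per_row: list[list[str] | None] = []
    for cell in table.df[column]:
        if is_missing(cell):
            parts_per_row.append(None)
            continue
        text = str(cell)
        if pattern.mode == "regex":
            parts = re.split(pattern.text, text, maxsplit=maxsplit)
        else:
            parts = text.split(pattern.text, maxsplit if maxsplit else -1)
        parts_per_row.append([p.strip() for p in parts])
    k = max((len(p) for p in parts_per_row if p is not None), default=1)
    out = table.copy()
    col_idx = out.columns.index(column)
    new_names = [f"{column}_{i + 1}" for i in range(k)]
    collisions = [n for n in new_names if n in out.columns and n != column]
    if collisions:
        raise OperationError(f"split would collide with existing column(s): {collisions}")
    new_data = {n: [None] * out.n_rows for n in new_names}
    for i, parts in enumerate(parts_per_row):
        if parts is None:
            continue
        for j, part in enumerate(parts):
            new_data[new_names[j]][i] = part or None
    before = out.columns[:col_idx]
    after = out.columns[col_idx + 1:]
    out.df = out.df.drop(columns=[column])
    for n in new_names:
        out.df[n] = new_data[n]
    out.df = out.df[list(before) + new_names + list(after)]
    out.validate()
    _record(
        recipe, "split_column", table_role,
        {"column": column, "pattern": _pattern_params(pattern),
         "max_parts": max_parts},
        out,
    )
    return out


def rename_column(
    table: AnnotationTable,
    old: str,
    new: str,
    *,
    recipe=None,
    table_role: str = "clinical",
) -> AnnotationTable:
    """Rename one column; values and order are untouched."""
    if old not in table.columns:
        raise OperationError(f"unknown column {old!r}")
    if new != old and new in table.columns:
        raise OperationError(f"column {new!r} already exists")
    out = table.copy()
    out.df = out.df.rename(columns={old: new})
    if out.id_column == old:
        out.id_column = new
    out.validate()
    _record(recipe, "rename_column", table_role, {"old": old, "new": new}, out)
    return out


def substitute(
    table: AnnotationTable,
    column: str,
    match: str,
    replacement: str,
    mode: str = "whole_cell_literal",
    *,
    recipe=None,
    table_role: str = "clinical",
) -> tuple[AnnotationTable, int]:
    """Replace values in one column; returns (table, count of changed cells).

    ``whole_cell_literal`` replaces a cell only when it equals *match*
    exactly; ``regex_substring`` rewrites every regex match within the cell.
    """
    if column not in table.columns:
        raise OperationError(f"unknown column {column!r}")
    if mode not in ("whole_cell_literal", "regex_substring"):
        raise OperationError(f"unknown substitute mode {mode!r}")
    if mode == "regex_substring":
        try:
            compiled = re.compile(match)
        except re.error as exc:
            raise OperationError(f"invalid regex {match!r}: {exc}") from exc
    out = table.copy()
    n_changed = 0
    new_values: list[object] = []
    for cell in out.df[column]:
        if is_missing(cell):
            new_values.append(None)
            continue
        text = str(cell)
        if mode == "whole_cell_literal":
            new = replacement if text == match else text
        else:
            new = compiled.sub(replacement, text)
        if new != text:
            n_changed += 1
        new_values.append(new if new != "" else None)
    out.df[column] = new_values
    out.validate()
    _record(
        recipe, "substitute", table_role,
        {"column": column, "match": match, "replacement": replacement,
         "mode": mode, "n_changed": n_changed},
        out,
    )
    return out, n_changed


def filter_rows_by_value(
    table: AnnotationTable,
    column: str,
    values: Sequence[str],
    *,
    recipe=None,
    table_role: str = "clinical",
) -> tuple[AnnotationTable, int]:
    """Exclude rows whose cell equals (whole-cell) any of *values*.

    Missing cells never match. Returns (table, removed count); survivor
    order is preserved and columns are untouched.
    """
    if column not in table.columns:
        raise OperationError(f"unknown column {column!r}")
    if not values:
        raise OperationError("values must be non-empty")
    targets = set(values)
    keep = [
        i
        for i in range(table.n_rows)
        if is_missing(table.df.at[i, column]) or str(table.df.at[i, column]) not in targets
    ]
    n_removed = table.n_rows - len(keep)
    out = table.copy()
    out.df = out.df.iloc[keep].reset_index(drop=True)
    out.validate()
    _record(
        recipe, "filter_rows_by_value", table_role,
        {"column": column, "values": list(values), "n_removed": n_removed},
        out,
    )
    return out, n_removed
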