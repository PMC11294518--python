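"""Provenance recipes: record, serialize, replay, and emit runnable scripts.

Every tidying, assay, merge, or export operation appends one event — the
operation name, its parameters, the table it touched, and the resulting
shape — to a :class:`Recipe`. A recipe is a small declarative document
(parameters only, never data), so it can be shared alongside a series
accession and replayed against the raw files to reproduce every exported
file byte-identically. ``generate_script`` additionally renders the recipe
as a standalone, commented Python script that calls the same public
operations in the same order.

Timestamps live only in the recipe header and never inside exported data
files, so replay output hashing is stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

from . import assay_ops, export_io, merge_ops, tidy_ops
from .model import AnnotationTable, GeoTidyError, Pattern, SeriesBundle

SCHEMA_VERSION = 1


class ReplayError(GeoTidyError):
    """A recipe could not be replayed against the given raw input."""


@dataclass
class RecipeEvent:
    op: str
    table: str            # which table role the op touched
    params: dict[str, Any]
    result: dict[str, int]  # rows/columns after the op

    def to_dict(self) -> dict:
        return {"op": self.op, "table": self.table,
                "params": self.params, "result": self.result}


@dataclass
class Recipe:
    series_accession: str = ""
    created: str = ""
    input_digest: str = ""
    events: list[RecipeEvent] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def add_event(self, op: str, table: str, params: dict, *, rows: int, columns: int) -> None:
        self.events.append(
            RecipeEvent(op, table, dict(params), {"rows": rows, "columns": columns})
        )

    def __len__(self) -> int:
        return len(self.events)


def serialize_recipe(recipe: Recipe) -> str:
    """Canonical JSON text; two serializations of equal recipes are byte-identical."""
    doc = {
        "schema_version": recipe.schema_version,
        "series_accession": recipe.series_accession,
        "created": recipe.created,
        "input_digest": recipe.input_digest,
        "events": [e.to_dict() for e in recipe.events],
    }
    return json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def parse_recipe(text: str) -> Recipe:
    doc = json.loads(text)
    for key in ("schema_version", "events"):
        if key not in doc:
            raise GeoTidyError(f"recipe document missing {key!r}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise GeoTidyError(
            f"unsupported recipe schema version {doc['schema_version']}"
        )
    events = [
        RecipeEvent(e["op"], e.get("table", "clinical"), dict(e.get("params", {})),
                    dict(e.get("result", {})))
        for e in doc["events"]
    ]
    return Recipe(
        series_accession=doc.get("series_accession", ""),
        created=doc.get("created", ""),
        input_digest=doc.get("input_digest", ""),
        events=events,
    )


def bundle_digest(bundle: SeriesBundle) -> str:
    """Content hash of the raw parsed tables (metadata excluded from nothing:
    the whole serialized series-matrix plus the platform table is hashed)."""
    from .geo_io import write_platform_table, write_series_matrix

    h = hashlib.sha256()
    h.update(write_series_matrix(bundle).encode("utf-8"))
    if bundle.features is not None:
        h.update(write_platform_table(bundle.features).encode("utf-8"))
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------

#: call-parameter whitelist per op; other recorded keys (counts, warnings)
#: are informational results, not arguments.
_REPLAY_PARAMS: dict[str, tuple[str, ...]] = {
    "drop_columns": ("names",),
    "drop_by_preset": ("presets",),
    "shift_cells": ("source_columns", "pattern", "new_column"),
    "split_key_value": ("column", "pattern"),
    "split_column": ("column", "pattern", "max_parts"),
    "rename_column": ("old", "new"),
    "substitute": ("column", "match", "replacement", "mode"),
    "filter_rows_by_value": ("column", "values"),
    "attach_feature_ids": ("target_id_column", "policy"),
    "summarize": ("stat",),
    "filter_assay_rows": ("column", "comparator", "threshold"),
    "transpose": (),
    "merge_tables": ("kind", "key"),
    "write_table": ("format", "filename"),
}

_TUPLE_RETURNING = {"drop_by_preset", "substitute", "filter_rows_by_value"}


def _revive(params: dict) -> dict:
    out = {}
    for k, v in params.items():
        if k == "pattern" and isinstance(v, dict):
            out[k] = Pattern(v["text"], v.get("mode", "literal"))
        else:
            out[k] = v
    return out


class Session:
    """A live tidying session over one series bundle.

    Operations applied through :meth:`apply` / :meth:`export` both mutate
    the session state and append to the session recipe, so the recipe can be
    replayed later against the raw input.
    """

    def __init__(self, bundle: SeriesBundle, outdir: str | Path | None = None):
        self.bundle = bundle.copy()
        self.merged: AnnotationTable | None = None
        self.outdir = None if outdir is None else Path(outdir)
        self.recipe = Recipe(
            series_accession=bundle.accession,
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            input_digest=bundle_digest(bundle),
        )

    # -- table plumbing ---------------------------------------------------
    def _get_table(self, role: str):
        if role == "clinical":
            return self.bundle.clinical
        if role == "features":
            if self.bundle.features is None:
                raise ReplayError("bundle has no feature table")
            return self.bundle.features
        if role == "assay":
            if self.bundle.assay is None:
                raise ReplayError("bundle has no assay matrix")
            return self.bundle.assay
        if role == "merged":
            if self.merged is None:
                raise ReplayError("no merged table exists yet")
            return self.merged
        raise ReplayError(f"unknown table role {role!r}")

    def _set_table(self, role: str, value) -> None:
        if role == "clinical":
            self.bundle.clinical = value
        elif role == "features":
            self.bundle.features = value
        elif role == "assay":
            self.bundle.assay = value
        elif role == "merged":
            self.merged = value

    # -- operations --------------------------------------------------------
    def apply(self, op: str, table_role: str = "clinical", **params):
        """Apply one named operation and record it."""
        if op == "merge_tables":
            spec = merge_ops.JoinSpec(
                params.get("kind", "inner"),
                params.get("key", self.bundle.clinical.id_column),
            )
            self.merged = merge_ops.merge_tables(
                self.bundle.clinical, self._get_table("assay"), spec,
                recipe=self.recipe,
            )
            return self.merged
        if hasattr(tidy_ops, op) and op in _REPLAY_PARAMS and table_role != "assay":
            func = getattr(tidy_ops, op)
            result = func(
                self._get_table(table_role), recipe=self.recipe,
                table_role=table_role, **_revive(params),
            )
            table = result[0] if op in _TUPLE_RETURNING else result
            self._set_table(table_role, table)
            return result
        if hasattr(assay_ops, op) and op in _REPLAY_PARAMS:
            func = getattr(assay_ops, op)
            if op == "attach_feature_ids":
                new = func(
                    self._get_table("assay"), self._get_table("features"),
                    recipe=self.recipe, **_revive(params),
                )
            else:
                new = func(self._get_table("assay"), recipe=self.recipe,
                           **_revive(params))
            self._set_table("assay", new)
            return new
        raise ReplayError(f"unknown operation {op!r}")

    def export(self, table_role: str, format: str, filename: str) -> Path:
        """Write one table into the session output directory and record it."""
        if self.outdir is None:
            raise ReplayError("session has no output directory")
        self.outdir.mkdir(parents=True, exist_ok=True)
        target = self.outdir / filename
        export_io.write_table(
            self._get_table(table_role), format, target,
            clinical=self.bundle.clinical if format == "brb" else None,
            recipe=self.recipe, table_role=table_role,
        )
        return target


def replay(
    recipe: Recipe,
    raw_bundle: SeriesBundle,
    outdir: str | Path | None = None,
    override_digest: bool = False,
) -> Session:
    """Re-run a recipe against a raw bundle, reproducing all exports.

    The raw bundle's content hash must match the recipe's ``input_digest``
    unless ``override_digest`` is set (in which case a mismatch only warns,
    and replay stops at the first inapplicable event rather than silently
    diverging).
    """
    import logging

    digest = bundle_digest(raw_bundle)
    if recipe.input_digest and digest != recipe.input_digest:
        if not override_digest:
            raise ReplayError(
                "input digest mismatch: recipe was recorded on different raw "
                "data (pass override_digest=True to replay anyway)"
            )
        logging.getLogger("geotidy").warning(
            "replaying despite input digest mismatch"
        )
    session = Session(raw_bundle, outdir)
    session.recipe = Recipe(
        series_accession=recipe.series_accession,
        created=session.recipe.created,
        input_digest=digest,
    )
    for i, event in enumerate(recipe.events):
        call = {k: event.params[k] for k in _REPLAY_PARAMS.get(event.op, ())
                if k in event.params}
        try:
            if event.op == "write_table":
                session.export(event.table, call["format"], call["filename"])
            else:
                session.apply(event.op, event.table, **call)
        except GeoTidyError as exc:
            raise ReplayError(f"event {i} ({event.op}): {exc}") from exc
    return session


# ---------------------------------------------------------------------------
# Script generation
# ---------------------------------------------------------------------------

_TASK_NAMES = {
    "drop_columns": "Select informative columns (remove listed columns)",
    "drop_by_preset": "Select informative columns (preset filters)",
    "shift_cells": "Shift cells into a single variable",
    "split_key_value": "Split key-value pairs",
    "split_column": "Split columns on a delimiter",
    "rename_column": "Rename a column",
    "substitute": "Substitute values",
    "filter_rows_by_value": "Filter samples",
    "attach_feature_ids": "Attach feature identifiers from the platform table",
    "summarize": "Summarize assay measurements per identifier",
    "filter_assay_rows": "Filter assay rows by threshold",
    "transpose": "Transpose the assay matrix",
    "merge_tables": "Merge clinical annotations with assay data",
    "write_table": "Save the data to a file",
}

_HEADER = '''\
"""Auto-generated tidying script.

Usage: python {name} <series_matrix.txt> <platform.txt|-> <outdir>

Replays a recorded tidying session against the raw series files, writing
every exported file into <outdir>.
"""
import sys
from pathlib import Path

from geotidy import assay_ops, export_io, merge_ops, tidy_ops
from geotidy.geo_io import parse_platform_table, parse_series_matrix
from geotidy.model import Pattern

series_path, platform_path, outdir = sys.argv[1], sys.argv[2], Path(sys.argv[3])
outdir.mkdir(parents=True, exist_ok=True)
bundle = parse_series_matrix(series_path)
if platform_path != "-":
    bundle.features = parse_platform_table(platform_path)
tables = {{"clinical": bundle.clinical, "features": bundle.features,
          "assay": bundle.assay, "merged": None}}
'''


def _pattern_expr(v: dict) -> str:
    return f"Pattern({v['text']!r}, {v.get('mode', 'literal')!r})"


def generate_script(recipe: Recipe, name: str = "tidy_steps.py") -> str:
    """Render the recipe as a standalone Python script.

    One commented block per event; comments name the tidying task and quote
    the operation parameters verbatim. Running the script on the raw fixture
    produces the same files as :func:`replay`.
    """
    lines = [_HEADER.format(name=name)]
    for event in recipe.events:
        call = {k: event.params[k] for k in _REPLAY_PARAMS.get(event.op, ())
                if k in event.params}
        lines.append(f"# {_TASK_NAMES.get(event.op, event.op)}")
        lines.append(f"# parameters: {json.dumps(event.params, sort_keys=True)}")
        args = []
        for k, v in call.items():
            if k == "pattern" and isinstance(v, dict):
                args.append(f"{k}={_pattern_expr(v)}")
            else:
                args.append(f"{k}={v!r}")
        argtext = ", ".join(args)
        role = event.table
        if event.op == "merge_tables":
            kind = call.get("kind", "inner")
            key = call.get("key", "geo_accession")
            lines.append(
                "tables['merged'] = merge_ops.merge_tables(tables['clinical'], "
                f"tables['assay'], merge_ops.JoinSpec({kind!r}, {key!r}))"
            )
        elif event.op == "write_table":
            fmt, fname = call["format"], call["filename"]
            clin = ", clinical=tables['clinical']" if fmt == "brb" else ""
            lines.append(
                f"export_io.write_table(tables[{role!r}], {fmt!r}, "
                f"outdir / {fname!r}{clin})"
            )
        elif event.op == "attach_feature_ids":
            lines.append(
                "tables['assay'] = assay_ops.attach_feature_ids("
                f"tables['assay'], tables['features'], {argtext})"
            )
        elif event.op in ("summarize", "filter_assay_rows", "transpose"):
            lines.append(
                f"tables['assay'] = assay_ops.{event.op}(tables['assay']"
                + (", " + argtext if argtext else "") + ")"
            )
        elif event.op in _TUPLE_RETURNING:
            lines.append(
                f"tables[{role!r}], _ = tidy_ops.{event.op}(tables[{role!r}], {argtext})"
            )
        else:
            lines.append(
                f"tables[{role!r}] = tidy_ops.{event.op}(tables[{role!r}], {argtext})"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
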