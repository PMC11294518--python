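"""Reading and writing GEO series-matrix and platform-annotation files.

A series-matrix file is tab-delimited text. Lines beginning ``!`` carry
series- and sample-level annotations; a processed-assay block may be
delimited by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``.
Roughly 30 % of series ship without the assay block (raw data often live in
a separate repository such as SRA), so the block is optional here too.

Repeated sample keys — most notably ``!Sample_characteristics_ch1``, which
submitters reuse once per free-form variable — expand into suffixed columns
(``characteristics_ch1``, ``characteristics_ch1.1``, ...) in file order.
"""

from __future__ import annotations

import gzip
import io
import logging
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_MISSING_TOKENS,
    AnnotationTable,
    AssayMatrix,
    IntegrityError,
    ParseError,
    PlatformLookupError,
    SeriesBundle,
    normalize_missing,
)

log = logging.getLogger("geotidy")

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _unquote(field: str) -> str:
    field = field.strip()
    if len(field) >= 2 and field[0] == '"' and field[-1] == '"':
        field = field[1:-1]
    return field


def _suffixed(name: str, seen: dict[str, int]) -> str:
    """First occurrence keeps the bare name; repeats get .1, .2, ... ."""
    n = seen.get(name, 0)
    seen[name] = n + 1
    return name if n == 0 else f"{name}.{n}"


def parse_series_matrix(
    source: str | Path | IO[str],
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
) -> SeriesBundle:
    """Parse one series-matrix file into a :class:`SeriesBundle`.

    ``!Series_*`` lines populate the metadata map (repeats joined with
    ``"; "``); ``!Sample_*`` lines become clinical columns with
    ``!Sample_geo_accession`` as the identifier; the optional table block
    becomes the assay matrix, with non-numeric cells coerced to missing
    (a count is logged).
    """
    stream = _open_text(source)
    metadata: dict[str, str] = {}
    sample_rows: list[tuple[str, list[str]]] = []  # (raw key, values) in file order
    assay_lines: list[tuple[int, list[str]]] = []
    in_table = False
    saw_table = False
    n_lines = 0

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        n_lines += 1
        low = line.strip().lower()
        if low == TABLE_BEGIN:
            in_table = True
            saw_table = True
            continue
        if low == TABLE_END:
            in_table = False
            continue
        if in_table:
            assay_lines.append((lineno, [_unquote(f) for f in line.split("\t")]))
            continue
        if line.startswith("!"):
            fields = [_unquote(f) for f in line.split("\t")]
            key = fields[0][1:]
            values = fields[1:]
            if key.startswith("Series_"):
                name = key[len("Series_"):]
                value = "; ".join(values) if values else ""
                if name in metadata:
                    metadata[name] = metadata[name] + "; " + value
                else:
                    metadata[name] = value
            elif key.startswith("Sample_"):
                sample_rows.append((key[len("Sample_"):], values))
        # non-'!' lines outside the table block are ignored (comments)

    if n_lines == 0:
        raise ParseError("empty stream: not a series-matrix file")
    if not sample_rows:
        raise ParseError("no !Sample_* lines found: not a series-matrix file")

    # Build the clinical table: one file line -> one column, suffixing repeats.
    seen: dict[str, int] = {}
    columns: list[str] = []
    column_values: list[list[str]] = []
    n_samples = max(len(v) for _, v in sample_rows)
    for key, values in sample_rows:
        columns.append(_suffixed(key, seen))
        padded = list(values) + [""] * (n_samples - len(values))
        column_values.append(padded)

    if "geo_accession" not in columns:
        raise ParseError("missing !Sample_geo_accession line")
    df = pd.DataFrame(
        {c: v for c, v in zip(columns, column_values)}, dtype=object
    )[columns]
    accessions = list(df["geo_accession"])
    if len(accessions) != len(set(accessions)):
        dupes = sorted({a for a in accessions if accessions.count(a) > 1})
        raise IntegrityError(f"duplicate sample accessions: {dupes}")
    clinical = AnnotationTable(
        normalize_missing(df, missing_tokens), id_column="geo_accession"
    )

    assay = _parse_assay_block(assay_lines, missing_tokens) if saw_table else None

    accession = metadata.get("geo_accession", "")
    platform = metadata.get("platform_id", "")
    if not platform:
        # fall back to the per-sample platform column if present
        for col in ("platform_id",):
            if col in clinical.columns:
                vals = [v for v in clinical.df[col] if v is not None]
                if vals:
                    platform = vals[0]
    return SeriesBundle(
        accession=accession,
        metadata=metadata,
        clinical=clinical,
        assay=assay,
        features=None,
        platform=platform,
    )


def _parse_assay_block(
    lines: list[tuple[int, list[str]]], missing_tokens: frozenset[str]
) -> AssayMatrix:
    if not lines:
        raise ParseError("assay table block is empty")
    header_lineno, header = lines[0]
    width = len(header)
    feature_id_column = header[0] or "ID_REF"
    sample_ids = header[1:]
    feature_ids: list[str] = []
    grid = np.full((len(lines) - 1, len(sample_ids)), np.nan)
    n_coerced = 0
    for i, (lineno, fields) in enumerate(lines[1:]):
        if len(fields) != width:
            raise ParseError(
                f"ragged assay row at line {lineno}: "
                f"expected {width} fields, got {len(fields)}"
            )
        feature_ids.append(fields[0])
        for j, cell in enumerate(fields[1:]):
            if cell.strip().lower() in missing_tokens:
                continue
            try:
                grid[i, j] = float(cell)
            except ValueError:
                n_coerced += 1
    if n_coerced:
        log.warning("assay parse: %d non-numeric cells coerced to missing", n_coerced)
    return AssayMatrix(
        feature_id_column=feature_id_column,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=grid,
    )


def parse_platform_table(
    source: str | Path | IO[str],
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
) -> AnnotationTable:
    """Parse a GPL platform-annotation table.

    Tab-delimited; leading ``#``-prefixed lines describe columns and are kept
    as column descriptions; the first non-comment row is the header; the
    first column is the feature identifier.
    """
    stream = _open_text(source)
    descriptions: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if header is None and line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                descriptions[k.strip()] = v.strip()
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if len(header) != len(set(header)):
                dupes = sorted({c for c in header if header.count(c) > 1})
                raise IntegrityError(f"duplicate column names in header: {dupes}")
            continue
        if len(fields) != len(header):
            raise ParseError(
                f"ragged platform row at line {lineno}: "
                f"expected {len(header)} fields, got {len(fields)}"
            )
        rows.append(fields)
    if header is None:
        raise ParseError("empty stream: no header row found")
    id_column = header[0]
    ids = [r[0] for r in rows]
    if len(ids) != len(set(ids)):
        dupes = sorted({v for v in ids if ids.count(v) > 1})
        raise IntegrityError(f"duplicate feature identifiers: {dupes}")
    df = pd.DataFrame(rows, columns=header, dtype=object)
    table = AnnotationTable(
        normalize_missing(df, missing_tokens), id_column=id_column
    )
    table.column_descriptions = descriptions
    return table


def select_platform(
    bundles: Sequence[SeriesBundle], platform_id: str | None = None
) -> SeriesBundle:
    """Pick one platform's bundle from a multi-platform series.

    With no ``platform_id`` the first bundle in listed order is returned,
    matching the convention of taking the first platform a series lists.
    """
    if not bundles:
        raise PlatformLookupError("no bundles to select from")
    if platform_id is None:
        return bundles[0]
    for b in bundles:
        if b.platform == platform_id:
            return b
    available = [b.platform for b in bundles]
    raise PlatformLookupError(
        f"platform {platform_id!r} not found; available: {available}"
    )


# ---------------------------------------------------------------------------
# Serialization back to the series-matrix dialect (round-trip support)
# ---------------------------------------------------------------------------

def _quote(value: object) -> str:
    return '"' + ("" if value is None else str(value)) + '"'


def write_series_matrix(bundle: SeriesBundle, stream: IO[str] | None = None) -> str:
    """Serialize *bundle* back to series-matrix text.

    ``parse_series_matrix(write_series_matrix(b))`` reproduces the clinical
    and assay tables cell for cell. Suffixed repeat columns (``name.1``)
    collapse back to repeated lines under the bare key.
    """
    out = io.StringIO()
    for key, value in bundle.metadata.items():
        out.write(f"!Series_{key}\t{_quote(value)}\n")
    clinical = bundle.clinical
    for col in clinical.columns:
        base = col.rsplit(".", 1)[0] if _is_suffixed(col) else col
        cells = "\t".join(_quote(v) for v in clinical.df[col])
        out.write(f"!Sample_{base}\t{cells}\n")
    if bundle.assay is not None:
        a = bundle.assay
        out.write(TABLE_BEGIN + "\n")
        out.write(
            "\t".join([_quote(a.feature_id_column)] + [_quote(s) for s in a.sample_ids])
            + "\n"
        )
        for i, fid in enumerate(a.feature_ids):
            cells = [
                "" if np.isnan(v) else repr(float(v)) for v in a.values[i]
            ]
            out.write("\t".join([_quote(fid)] + cells) + "\n")
        out.write(TABLE_END + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def _is_suffixed(col: str) -> bool:
    head, sep, tail = col.rpartition(".")
    return bool(sep) and tail.isdigit()


def write_platform_table(table: AnnotationTable, stream: IO[str] | None = None) -> str:
    """Serialize a feature table back to the GPL tab-delimited dialect."""
    out = io.StringIO()
    for k, v in table.column_descriptions.items():
        out.write(f"#{k} = {v}\n")
    out.write("\t".join(table.columns) + "\n")
    for _, row in table.df.iterrows():
        out.write("\t".join("" if v is None else str(v) for v in row) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def fetch_series_matrix(accession: str, dest_dir: str | Path) -> list[Path]:
    """Download series-matrix file(s) for a GSE accession from NCBI's FTP
    mirror over HTTPS. Network plumbing only; every tested path uses the
    synthetic fixture generator instead.
    """
    import urllib.request

    accession = accession.upper()
    if not accession.startswith("GSE"):
        raise ValueError("accession must be GSE-prefixed")
    stem = accession[:-3] + "nnn"
    base = (
        f"https://ftp.ncbi.nlm.nih.gov/geo/series/{stem}/{accession}/matrix/"
    )
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    listing = urllib.request.urlopen(base).read().decode("utf-8", "replace")
    names = sorted(
        {
            tok
            for tok in listing.replace('"', " ").replace(">", " ").split()
            if tok.startswith(accession) and tok.endswith("_series_matrix.txt.gz")
        }
    )
    paths = []
    for name in names:
        target = dest / name
        urllib.request.urlretrieve(base + name, target)
        paths.append(target)
    return paths
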