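"""Core data model for tidying GEO series.

A GEO series bundles three tables: sample-level ("clinical") annotations,
an optional numeric assay matrix, and platform ("feature") annotations.
``AnnotationTable`` holds the two annotation tables; ``AssayMatrix`` holds
the measurements; ``SeriesBundle`` ties them together for one platform.

Missing values: cells equal to any token in the configured missing-token
set (case-insensitive, whitespace-stripped) are normalized to ``None`` at
construction time. GEO submitters vary widely in how they mark absence, so
the default set covers the common spellings and is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Tokens treated as missing on parse (compared case-insensitively after
#: stripping surrounding whitespace).
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "na", "n/a", "null", "--"})

FEATURES_BY_SAMPLES = "features_by_samples"
SAMPLES_BY_FEATURES = "samples_by_features"


class GeoTidyError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GeoTidyError):
    """Malformed input file (ragged table block, empty stream, ...)."""


class IntegrityError(GeoTidyError):
    """A table invariant is violated (duplicate ids, duplicate columns, ...)."""


class OperationError(GeoTidyError):
    """An operation was invoked with invalid arguments or state."""


class PlatformLookupError(GeoTidyError):
    """Requested platform id is not among the parsed bundles."""


def is_missing(cell: object, tokens: frozenset[str] = DEFAULT_MISSING_TOKENS) -> bool:
    """True when *cell* represents a missing value."""
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return str(cell).strip().lower() in tokens


def normalize_missing(
    df: pd.DataFrame, tokens: frozenset[str] = DEFAULT_MISSING_TOKENS
) -> pd.DataFrame:
    """Copy *df* with every missing-token cell replaced by ``None``."""
    out = df.copy()
    for col in out.columns:
        out[col] = [
            None if is_missing(v, tokens) else (v if isinstance(v, str) else str(v))
            for v in out[col]
        ]
    return out.astype(object)


@dataclass
class AnnotationTable:
    """Rectangular table of observations (samples or features) x variables.

    ``df`` is an object-dtype DataFrame with ``None`` for missing cells and a
    default RangeIndex; ``id_column`` names the identifier variable whose
    values must be unique and never missing.
    """

    df: pd.DataFrame
    id_column: str
    column_descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True).astype(object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        cols = list(self.df.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise IntegrityError(f"duplicate column names: {dupes}")
        if self.id_column not in cols:
            raise IntegrityError(f"id column {self.id_column!r} not in table")
        ids = list(self.df[self.id_column])
        if any(v is None for v in ids):
            raise IntegrityError(f"missing value in id column {self.id_column!r}")
        if len(ids) != len(set(ids)):
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise IntegrityError(f"duplicate identifiers in {self.id_column!r}: {dupes}")

    # -- conveniences ----------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def copy(self) -> "AnnotationTable":
        return AnnotationTable(
            self.df.copy(), self.id_column, dict(self.column_descriptions)
        )

    def cell(self, row: int, column: str) -> object:
        return self.df.at[row, column]

    def equals(self, other: "AnnotationTable") -> bool:
        if self.id_column != other.id_column:
            return False
        if self.columns != other.columns or self.n_rows != other.n_rows:
            return False
        a = self.df.to_numpy(dtype=object)
        b = other.df.to_numpy(dtype=object)
        return all(
            (x is None and y is None) or x == y for x, y in zip(a.ravel(), b.ravel())
        )

    @classmethod
    def from_rows(
        cls,
        columns: Sequence[str],
        rows: Iterable[Sequence[object]],
        id_column: str,
        missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
    ) -> "AnnotationTable":
        df = pd.DataFrame(list(rows), columns=list(columns), dtype=object)
        return cls(normalize_missing(df, missing_tokens), id_column)


@dataclass
class AssayMatrix:
    """Numeric measurements, features x samples, with missing entries as NaN.

    Values are stored canonically as a (n_features, n_samples) float array;
    the ``orientation`` flag says which way the matrix is presented (and
    exported). ``group_keys``, when set by ``assay_ops.attach_feature_ids``,
    aligns a summarization key (e.g. gene symbol) to each feature row;
    ``group_name`` records which platform column supplied it.
    """

    feature_id_column: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    orientation: str = FEATURES_BY_SAMPLES
    group_keys: list[str] | None = None
    group_name: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise IntegrityError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample ids in assay matrix")
        if self.orientation not in (FEATURES_BY_SAMPLES, SAMPLES_BY_FEATURES):
            raise OperationError(f"unknown orientation {self.orientation!r}")
        if self.group_keys is not None and len(self.group_keys) != len(self.feature_ids):
            raise IntegrityError("group_keys length does not match feature rows")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        """Presented shape, respecting orientation."""
        if self.orientation == FEATURES_BY_SAMPLES:
            return (self.n_features, self.n_samples)
        return (self.n_samples, self.n_features)

    def copy(self) -> "AssayMatrix":
        return replace(
            self,
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            group_keys=None if self.group_keys is None else list(self.group_keys),
        )

    def to_frame(self) -> pd.DataFrame:
        """Presented table: id column first, then one column per observation."""
        if self.orientation == FEATURES_BY_SAMPLES:
            df = pd.DataFrame(self.values, columns=self.sample_ids)
            df.insert(0, self.feature_id_column, self.feature_ids)
            return df
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise IntegrityError(
                "duplicate feature ids cannot become column headers; "
                "summarize the assay first"
            )
        df = pd.DataFrame(self.values.T, columns=self.feature_ids)
        df.insert(0, "geo_accession", self.sample_ids)
        return df


@dataclass
class SeriesBundle:
    """One GEO series, restricted to a single platform."""

    accession: str
    metadata: dict[str, str]
    clinical: AnnotationTable
    assay: AssayMatrix | None = None
    features: AnnotationTable | None = None
    platform: str = ""

    def __post_init__(self) -> None:
        if self.assay is not None:
            known = set(self.clinical.df[self.clinical.id_column])
            extra = [s for s in self.assay.sample_ids if s not in known]
            if extra:
                raise IntegrityError(
                    f"assay samples absent from clinical table: {extra}"
                )

    def copy(self) -> "SeriesBundle":
        return SeriesBundle(
            self.accession,
            dict(self.metadata),
            self.clinical.copy(),
            None if self.assay is None else self.assay.copy(),
            None if self.features is None else self.features.copy(),
            self.platform,
        )


@dataclass(frozen=True)
class Pattern:
    """A literal string or regular expression used by the tidying operations.

    Literal mode matches by substring containment; regex mode uses
    ``re.search`` semantics.
    """

    text: str
    mode: str = "literal"

    def __post_init__(self) -> None:
        if self.mode not in ("literal", "regex"):
            raise OperationError(f"unknown pattern mode {self.mode!r}")
        if self.mode == "regex":
            import re

            try:
                re.compile(self.text)
            except re.error as exc:
                raise OperationError(f"invalid regex {self.text!r}: {exc}") from exc


def as_pattern(pattern: "Pattern | str", mode: str = "literal") -> Pattern:
    if isinstance(pattern, Pattern):
        return pattern
    return Pattern(str(pattern), mode)
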