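"""Per-column summaries: type inference, histograms, category counts.

A numeric column (every non-missing cell parses as a number) is profiled as
a histogram whose bin width the caller chooses (Sturges' rule by default);
anything else is profiled as category counts, sorted by descending count
then name. Profiles can be rendered to PDF/JPG/PNG bar charts with a chosen
color, pixel size, and font size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import AnnotationTable, OperationError, is_missing
from . import tidy_ops

RENDER_FORMATS = ("pdf", "jpg", "png")


@dataclass
class ColumnProfile:
    column: str
    inferred_type: str  # numeric | categorical | date | url | identifier
    n_missing: int
    n_rows: int
    bin_edges: list[float] = field(default_factory=list)
    bin_counts: list[int] = field(default_factory=list)
    bin_width: float | None = None
    category_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_numeric(self) -> bool:
        return self.inferred_type == "numeric"


def _numeric_values(cells: list[object]) -> list[float] | None:
    out = []
    for c in cells:
        try:
            out.append(float(str(c)))
        except ValueError:
            return None
    return out


def infer_type(cells: list[object]) -> str:
    """Type inference using the same predicates as the column presets."""
    present = [c for c in cells if not is_missing(c)]
    if not present:
        return "categorical"
    if tidy_ops.is_web_addresses(present):
        return "url"
    if tidy_ops.is_dates(present):
        return "date"
    if _numeric_values(present) is not None:
        return "numeric"
    if tidy_ops.is_all_unique(present):
        return "identifier"
    return "categorical"


def profile_column(
    table: AnnotationTable, column: str, bin_width: float | None = None
) -> ColumnProfile:
    """Summarize one column.

    Numeric columns get uniform bins ``[min + k*w, min + (k+1)*w)`` with the
    last bin closed; the default width follows Sturges' rule. Other columns
    get category counts. Bin/category counts plus the missing count always
    equal the row count.
    """
    if column not in table.columns:
        raise OperationError(f"unknown column {column!r}")
    if bin_width is not None and bin_width <= 0:
        raise OperationError("bin_width must be > 0")
    cells = list(table.df[column])
    present = [c for c in cells if not is_missing(c)]
    n_missing = len(cells) - len(present)
    inferred = infer_type(cells)
    profile = ColumnProfile(column, inferred, n_missing, len(cells))
    if inferred == "numeric":
        values = np.asarray(_numeric_values(present), dtype=float)
        lo, hi = float(values.min()), float(values.max())
        if bin_width is None:
            n_bins = max(1, int(math.ceil(math.log2(len(values)) + 1)))
            bin_width = (hi - lo) / n_bins if hi > lo else 1.0
        k = max(1, int(math.ceil((hi - lo) / bin_width))) if hi > lo else 1
        edges = [lo + i * bin_width for i in range(k + 1)]
        counts, _ = np.histogram(values, bins=edges)
        profile.bin_edges = edges
        profile.bin_counts = [int(c) for c in counts]
        profile.bin_width = float(bin_width)
    else:
        if bin_width is not None:
            raise OperationError(
                f"bin_width given but column {column!r} is {inferred}, not numeric"
            )
        counts: dict[str, int] = {}
        for c in present:
            counts[str(c)] = counts.get(str(c), 0) + 1
        profile.category_counts = dict(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
    return profile


def render_profile(
    profile: ColumnProfile,
    path: str | Path,
    *,
    format: str | None = None,
    color: str = "#4878A8",
    width_px: int = 640,
    height_px: int = 480,
    font_size: int = 10,
) -> Path:
    """Render a profile to a PDF/JPG/PNG bar chart and return the path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "jpeg":
        fmt = "jpg"
    if fmt not in RENDER_FORMATS:
        raise OperationError(f"unknown format {fmt!r}; supported: {RENDER_FORMATS}")
    dpi = 100
    fig, ax = plt.subplots(figsize=(width_px / dpi, height_px / dpi), dpi=dpi)
    try:
        if profile.is_numeric:
            lefts = profile.bin_edges[:-1]
            ax.bar(lefts, profile.bin_counts, width=profile.bin_width,
                   align="edge", color=color, edgecolor="white")
            ax.set_xlabel(profile.column, fontsize=font_size)
            ax.set_ylabel("count", fontsize=font_size)
        else:
            names = list(profile.category_counts)
            ax.bar(range(len(names)), list(profile.category_counts.values()),
                   color=color)
            ax.set_xticks(range(len(names)))
            ax.set_xticklabels(names, rotation=45, ha="right", fontsize=font_size)
            ax.set_ylabel("count", fontsize=font_size)
        ax.tick_params(labelsize=font_size)
        fig.tight_layout()
        fig.savefig(path, format="jpeg" if fmt == "jpg" else fmt, dpi=dpi)
    finally:
        plt.close(fig)
    return path
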