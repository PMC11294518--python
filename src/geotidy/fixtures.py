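"""Deterministic synthetic GEO fixtures exhibiting the catalogued pathologies.

Real series-matrix files are messy in recurring ways: characteristics cells
holding key-value pairs or several delimited values, annotations drifting
leftward across columns when values are missing, uninformative constant /
unique / date / URL columns, and inconsistent vocabularies for the same
concept ("Relapse" vs "Yes"). This module writes small series-matrix and
platform files that exhibit any requested subset of those pathologies, plus
a ground-truth ledger: the clean table a tidier should recover and the
minimal operation sequence that recovers it.

The ledger's clean table is computed by a ~60-line naive interpreter private
to this module — deliberately independent of :mod:`geotidy.tidy_ops` — so
closed-loop tests (tidy(pathological) == clean) compare two routes.

Same spec + seed always produces byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import AnnotationTable, OperationError, SeriesBundle

PATHOLOGIES = (
    "key_value_pairs",
    "multi_value_cells",
    "shifted_cells",
    "constant_columns",
    "unique_columns",
    "date_columns",
    "url_columns",
    "vocabulary_drift",
    "duplicate_gene_mapping",
    "missing_assay",
)

#: Vocabulary pools mirroring real submitter drift.
SEX_TERMS = ("female", "male")
DRUG_TERMS = ("anastrozole", "tamoxifen", "letrozole")
GRADE_TERMS = ("G1", "G2", "G3")
RELAPSE_CANONICAL = {"relapse": "Relapse", "non_relapse": "Non-relapse"}
RELAPSE_DRIFTED = {"relapse": "Yes", "non_relapse": "No"}
DATE_POOL = ("Jan 05 2018", "Mar 14 2019", "Jul 22 2020", "Nov 30 2021")


@dataclass(frozen=True)
class PathologySpec:
    n_samples: int = 6
    n_features: int = 12
    pathologies: tuple[str, ...] = ()
    seed: int = 0
    drift_rate: float = 0.4  # fraction of cells using the drifted vocabulary

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise OperationError("n_samples must be >= 2")
        unknown = [p for p in self.pathologies if p not in PATHOLOGIES]
        if unknown:
            raise OperationError(f"unknown pathologies: {unknown}")
        if "missing_assay" in self.pathologies and "duplicate_gene_mapping" in self.pathologies:
            raise OperationError(
                "contradictory spec: duplicate_gene_mapping needs an assay block, "
                "missing_assay removes it"
            )


@dataclass
class FixtureLedger:
    """Ground truth for one generated fixture."""

    spec: PathologySpec
    clean_clinical: AnnotationTable
    operations: list[dict]           # recipe-shaped: {op, table, params}
    dirty_columns: list[str]
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    shifted_rows: list[int] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.spec.n_samples


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_series(spec: PathologySpec) -> tuple[str, str, FixtureLedger]:
    """Emit (series-matrix text, platform text, ledger) for *spec*."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    p = set(spec.pathologies)

    accessions = [f"GSM{1000 + i}" for i in range(1, n + 1)]
    titles = [f"Sample {i}" for i in range(1, n + 1)]
    sex = [SEX_TERMS[i % 2] for i in range(n)]
    age = [int(v) for v in rng.integers(40, 76, size=n)]
    drug = [DRUG_TERMS[i % len(DRUG_TERMS)] for i in range(n)]
    grade = [GRADE_TERMS[i % len(GRADE_TERMS)] for i in range(n)]
    relapsed = [bool(v) for v in rng.random(n) < 0.5]

    # sample lines in file order: (raw key, cell values)
    sample_lines: list[tuple[str, list[str]]] = [
        ("title", titles),
        ("geo_accession", accessions),
    ]
    char_names: list[str] = []  # suffixed names in parse order

    def add_characteristics(cells: list[str]) -> str:
        sample_lines.append(("characteristics_ch1", cells))
        name = (
            "characteristics_ch1"
            if not char_names
            else f"characteristics_ch1.{len(char_names)}"
        )
        char_names.append(name)
        return name

    operations: list[dict] = []
    kv_col = mv_col = vd_col = None
    shift_a = shift_b = None
    shifted_rows: list[int] = []

    if "key_value_pairs" in p:
        kv_col = add_characteristics([f"sex: {s}" for s in sex])
    if "multi_value_cells" in p:
        mv_col = add_characteristics(
            [f"age = {a}; drug = {d}" for a, d in zip(age, drug)]
        )
    if "shifted_cells" in p:
        shifted_rows = sorted(
            rng.choice(n, size=max(1, n // 3), replace=False).tolist()
        )
        col_a = ["" if i in shifted_rows else f"grade: {g}"
                 for i, g in enumerate(grade)]
        col_b = [f"grade: {g}" if i in shifted_rows else ""
                 for i, g in enumerate(grade)]
        shift_a = add_characteristics(col_a)
        shift_b = add_characteristics(col_b)
    if "vocabulary_drift" in p:
        drifted = rng.random(n) < spec.drift_rate
        if not drifted.any():
            drifted[-1] = True
        cells = []
        for r, d in zip(relapsed, drifted):
            status = "relapse" if r else "non_relapse"
            cells.append((RELAPSE_DRIFTED if d else RELAPSE_CANONICAL)[status])
        vd_col = add_characteristics(cells)
    if "constant_columns" in p:
        sample_lines.append(("molecule_ch1", ["total RNA"] * n))
    if "unique_columns" in p:
        sample_lines.append(
            ("description", [f"patient-{i:04d}" for i in range(1, n + 1)])
        )
    if "date_columns" in p:
        dates = [DATE_POOL[int(v)] for v in rng.integers(0, len(DATE_POOL), size=n)]
        sample_lines.append(("last_update_date", dates))
    if "url_columns" in p:
        sample_lines.append(
            (
                "supplementary_file",
                [
                    f"ftp://ftp.ncbi.nlm.nih.gov/geo/samples/{a}/suppl/{a}.CEL.gz"
                    for a in accessions
                ],
            )
        )

    # ---- recovery operation sequence -----------------------------------
    if shift_a is not None:
        operations.append(
            {"op": "shift_cells", "table": "clinical",
             "params": {"source_columns": [shift_a, shift_b],
                        "pattern": {"text": "^grade:", "mode": "regex"},
                        "new_column": "grade_raw"}}
        )
        operations.append(
            {"op": "drop_columns", "table": "clinical",
             "params": {"names": [shift_a, shift_b]}}
        )
        operations.append(
            {"op": "split_key_value", "table": "clinical",
             "params": {"column": "grade_raw",
                        "pattern": {"text": ":", "mode": "literal"}}}
        )
    if kv_col is not None:
        operations.append(
            {"op": "split_key_value", "table": "clinical",
             "params": {"column": kv_col,
                        "pattern": {"text": ":", "mode": "literal"}}}
        )
    if mv_col is not None:
        operations.append(
            {"op": "split_column", "table": "clinical",
             "params": {"column": mv_col,
                        "pattern": {"text": ";", "mode": "literal"},
                        "max_parts": None}}
        )
        for part in (1, 2):
            operations.append(
                {"op": "split_key_value", "table": "clinical",
                 "params": {"column": f"{mv_col}_{part}",
                            "pattern": {"text": "=", "mode": "literal"}}}
            )
    if vd_col is not None:
        for wrong, right in (("Yes", "Relapse"), ("No", "Non-relapse")):
            operations.append(
                {"op": "substitute", "table": "clinical",
                 "params": {"column": vd_col, "match": wrong,
                            "replacement": right, "mode": "whole_cell_literal"}}
            )
        operations.append(
            {"op": "rename_column", "table": "clinical",
             "params": {"old": vd_col, "new": "relapse_status"}}
        )
    presets = [
        name
        for flag, name in (
            ("constant_columns", "same_value"),
            ("unique_columns", "all_unique"),
            ("date_columns", "dates"),
            ("url_columns", "web_addresses"),
        )
        if flag in p
    ]
    if presets:
        operations.append(
            {"op": "drop_by_preset", "table": "clinical",
             "params": {"presets": presets}}
        )

    # ---- serialize the series-matrix text ------------------------------
    seed_tag = spec.seed % 100000
    accession = f"GSE{90000 + seed_tag % 10000}"
    platform_id = f"GPL{500 + seed_tag % 100}"
    lines = [
        f'!Series_title\t"Synthetic fixture series (seed {spec.seed})"',
        f'!Series_geo_accession\t"{accession}"',
        '!Series_organism\t"Homo sapiens"',
        '!Series_type\t"Expression profiling by array"',
        '!Series_summary\t"Synthetic series emulating common annotation pathologies."',
        f'!Series_platform_id\t"{platform_id}"',
    ]
    for key, cells in sample_lines:
        quoted = "\t".join(f'"{c}"' for c in cells)
        lines.append(f"!Sample_{key}\t{quoted}")

    probe_to_gene: dict[str, str] = {}
    platform_lines = [
        "#ID = unique feature (probe set) identifier",
        "#GENE_SYMBOL = official gene symbol mapped to the probe set",
        "#SPECIES = organism of the probe sequence",
        "ID\tGENE_SYMBOL\tSPECIES",
    ]
    probes = [f"P{i:04d}" for i in range(1, spec.n_features + 1)]
    for j, probe in enumerate(probes):
        if "duplicate_gene_mapping" in p:
            gene = f"GENE{j // 2 + 1}"
        else:
            gene = f"GENE{j + 1}"
        probe_to_gene[probe] = gene
        platform_lines.append(f"{probe}\t{gene}\tHomo sapiens")

    if "missing_assay" not in p:
        lines.append("!series_matrix_table_begin")
        header = "\t".join(['"ID_REF"'] + [f'"{a}"' for a in accessions])
        lines.append(header)
        values = np.round(
            np.exp(rng.normal(2.0, 0.6, size=(spec.n_features, n))), 4
        )
        for probe, row in zip(probes, values):
            lines.append("\t".join([f'"{probe}"'] + [f"{v:.4f}" for v in row]))
        lines.append("!series_matrix_table_end")

    series_text = "\n".join(lines) + "\n"
    platform_text = "\n".join(platform_lines) + "\n"

    # ---- dirty table as parsed, then the naive clean-table oracle -------
    dirty_cols: list[tuple[str, list[object]]] = []
    seen: dict[str, int] = {}
    for key, cells in sample_lines:
        count = seen.get(key, 0)
        seen[key] = count + 1
        name = key if count == 0 else f"{key}.{count}"
        dirty_cols.append((name, [c if c != "" else None for c in cells]))
    clean_cols = _naive_apply(dirty_cols, operations, id_column="geo_accession")
    clean_clinical = AnnotationTable.from_rows(
        [name for name, _ in clean_cols],
        list(zip(*[vals for _, vals in clean_cols])),
        id_column="geo_accession",
    )

    ledger = FixtureLedger(
        spec=spec,
        clean_clinical=clean_clinical,
        operations=operations,
        dirty_columns=[name for name, _ in dirty_cols],
        probe_to_gene=probe_to_gene,
        shifted_rows=shifted_rows,
    )
    return series_text, platform_text, ledger


# ---------------------------------------------------------------------------
# Naive oracle: a minimal, independent re-statement of each recovery step
# ---------------------------------------------------------------------------

Cols = list[tuple[str, list[object]]]


def _naive_apply(cols: Cols, operations: list[dict], id_column: str) -> Cols:
    cols = [(n, list(v)) for n, v in cols]
    for event in operations:
        op, prm = event["op"], event["params"]
        names = [n for n, _ in cols]
        if op == "shift_cells":
            pat = re.compile(prm["pattern"]["text"])
            sources = prm["source_columns"]
            n_rows = len(cols[0][1])
            new = [None] * n_rows
            lookup = dict(cols)
            for i in range(n_rows):
                for s in sources:
                    v = lookup[s][i]
                    if v is not None and pat.search(str(v)):
                        new[i] = v
                        lookup[s][i] = None
                        break
            cols.append((prm["new_column"], new))
        elif op == "drop_columns":
            cols = [(n, v) for n, v in cols if n not in prm["names"]]
        elif op == "split_key_value":
            delim = prm["pattern"]["text"]
            out: Cols = []
            for n, v in cols:
                if n != prm["column"]:
                    out.append((n, v))
                    continue
                key = None
                vals = []
                for cell in v:
                    if cell is None:
                        vals.append(None)
                        continue
                    k, _, rest = str(cell).partition(delim)
                    key = k.strip()
                    vals.append(rest.strip() or None)
                out.append((key if key else n, vals))
            cols = out
        elif op == "split_column":
            delim = prm["pattern"]["text"]
            out = []
            for n, v in cols:
                if n != prm["column"]:
                    out.append((n, v))
                    continue
                split = [None if c is None else [s.strip() for s in str(c).split(delim)]
                         for c in v]
                k = max(len(s) for s in split if s is not None)
                for j in range(k):
                    out.append(
                        (f"{n}_{j + 1}",
                         [None if s is None or j >= len(s) else (s[j] or None)
                          for s in split])
                    )
            cols = out
        elif op == "substitute":
            cols = [
                (n, [prm["replacement"] if c == prm["match"] else c for c in v]
                 if n == prm["column"] else v)
                for n, v in cols
            ]
        elif op == "rename_column":
            cols = [(prm["new"] if n == prm["old"] else n, v) for n, v in cols]
        elif op == "drop_by_preset":
            cols = [
                (n, v) for n, v in cols
                if n == id_column or not _naive_preset_match(v, prm["presets"])
            ]
        else:  # pragma: no cover - generator only emits the ops above
            raise OperationError(f"naive oracle cannot apply {op!r}")
    return cols


_NAIVE_DATE = re.compile(r"^[A-Z][a-z]{2} \d{2} \d{4}$")


def _naive_preset_match(values: list[object], presets: list[str]) -> bool:
    present = [str(v) for v in values if v is not None]
    for preset in presets:
        if preset == "same_value" and len(set(present)) <= 1:
            return True
        if preset == "all_unique" and present and len(set(present)) == len(present):
            return True
        if preset == "dates" and present and all(_NAIVE_DATE.match(v) for v in present):
            return True
        if preset == "web_addresses" and present and all(
            v.startswith(("http://", "https://", "ftp://")) for v in present
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# Detectors: does the emitted file actually exhibit the pathology?
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r"^[a-z_]+\s*[:=]\s*.+$")


def pathology_present(bundle: SeriesBundle, pathology: str, ledger: FixtureLedger) -> bool:
    """True when the parsed *bundle* demonstrably exhibits *pathology*."""
    from . import tidy_ops

    clin = bundle.clinical
    cols = [c for c in clin.columns if c != clin.id_column]

    def col_values(name: str) -> list[str]:
        return [str(v) for v in clin.df[name] if v is not None]

    if pathology == "key_value_pairs":
        return any(
            vals and all(_KV_RE.match(v) for v in vals)
            for vals in (col_values(c) for c in cols)
        )
    if pathology == "multi_value_cells":
        return any(";" in v for c in cols for v in col_values(c))
    if pathology == "shifted_cells":
        pat = re.compile("^grade:")
        hits = [
            (c, i)
            for c in cols
            for i, v in enumerate(clin.df[c])
            if v is not None and pat.search(str(v))
        ]
        return len({c for c, _ in hits}) > 1  # same variable in >1 column
    if pathology == "constant_columns":
        return any(tidy_ops.is_same_value(clin.df[c]) for c in cols)
    if pathology == "unique_columns":
        return any(tidy_ops.is_all_unique(clin.df[c]) for c in cols)
    if pathology == "date_columns":
        return any(tidy_ops.is_dates(clin.df[c]) for c in cols)
    if pathology == "url_columns":
        return any(tidy_ops.is_web_addresses(clin.df[c]) for c in cols)
    if pathology == "vocabulary_drift":
        for c in cols:
            vals = set(col_values(c))
            if (vals & {"Relapse", "Non-relapse"}) and (vals & {"Yes", "No"}):
                return True
        return False
    if pathology == "duplicate_gene_mapping":
        genes = list(ledger.probe_to_gene.values())
        return len(genes) != len(set(genes))
    if pathology == "missing_assay":
        return bundle.assay is None
    raise OperationError(f"unknown pathology {pathology!r}")


def write_fixture(spec: PathologySpec, outdir: str | Path) -> tuple[Path, Path, FixtureLedger]:
    """Write the fixture files to disk; returns (series path, platform path, ledger)."""
    series_text, platform_text, ledger = generate_series(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_path = outdir / f"fixture_seed{spec.seed}_series_matrix.txt"
    platform_path = outdir / f"fixture_seed{spec.seed}_platform.txt"
    series_path.write_text(series_text, encoding="utf-8")
    platform_path.write_text(platform_text, encoding="utf-8")
    return series_path, platform_path, ledger
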