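# geotidy

Tidy [Gene Expression Omnibus](https://www.ncbi.nlm.nih.gov/geo/) (GEO)
series into analysis-ready tables — as a Python library and a `geotidy`
command line.

GEO distributes each series as a *series-matrix* file: `!`-prefixed
metadata and sample-annotation lines, optionally followed by a processed
assay block. The sample-level ("clinical") annotations are free-form and
almost always need cleaning before analysis: several values packed into one
cell (`"female; 52; anastrozole"`), key-value cells (`"sex = female"`),
values drifting leftward across columns when data are missing,
uninformative constant / unique / date / URL columns, and inconsistent
vocabularies across studies (`"Relapse"` vs `"Yes"`). Assay data bring
their own chore: microarray measurements arrive per probe set, while most
analyses want one row per gene.

`geotidy` covers that whole pipeline:

- **geo_io** — parse series-matrix and GPL platform-annotation files into a
  `SeriesBundle` (clinical `AnnotationTable`, numeric `AssayMatrix`,
  feature `AnnotationTable`); pick one platform when a series lists several
  (first listed, by default).
- **tidy_ops** — the eight clinical-tab operations, as pure
  table-to-table transformations that apply equally to platform tables:
  drop columns (by name or by preset — all-same, all-unique, dates, web
  addresses), shift drifted cells into one column, split key-value pairs,
  split delimited cells, rename, substitute values, filter samples.
- **assay_ops** — attach gene (or any platform) identifiers to probe rows,
  collapse each group by mean / median / min / max (or relabel with
  *keep all*), filter rows by threshold, transpose.
- **merge_ops** — inner / left / right / full join of clinical annotations
  with samples-by-features assay data.
- **export_io** — write any table as CSV, TSV, JSON, Excel, or the
  BRB-ArrayTools paired expression/covariate files; read the text formats
  back.
- **recipe** — every operation is recorded into a small declarative
  `Recipe`; replaying it against the raw files reproduces each exported
  file byte-identically, and `generate_script` renders it as a standalone,
  commented Python script.
- **profiling** — per-column type inference, histograms with a
  user-selected bin width, category counts, and PDF/JPG/PNG charts.
- **fixtures** — a deterministic generator of synthetic series-matrix +
  platform files exhibiting any subset of the pathologies above, with a
  ground-truth ledger (the clean table and the operation sequence that
  recovers it), so everything is testable offline.

## Worked example

Generate a small synthetic series whose characteristics columns hold
key-value pairs and a drifting relapse vocabulary, then tidy it:

```bash
$ geotidy fixture --samples 4 --pathologies key_value_pairs,vocabulary_drift \
      --seed 5 -o demo
$ geotidy clinical demo/fixture_seed5_series_matrix.txt \
      --op split-key-value --column characteristics_ch1 --delim ":"
title	geo_accession	sex	characteristics_ch1.1
Sample 1	GSM1001	female	Non-relapse
Sample 2	GSM1002	male	Yes
Sample 3	GSM1003	female	Yes
Sample 4	GSM1004	male	Relapse
```

The key-value column became a named `sex` column holding only the values.
The second characteristics column still mixes two vocabularies for the same
concept; profiling shows it directly:

```bash
$ geotidy profile demo/fixture_seed5_series_matrix.txt --column characteristics_ch1.1
{
  "column": "characteristics_ch1.1",
  "inferred_type": "categorical",
  "n_missing": 0,
  "counts": {
    "Yes": 2,
    "Non-relapse": 1,
    "Relapse": 1
  }
}
```

`--op substitute --column characteristics_ch1.1 --match Yes --replacement
Relapse` (and likewise `No` → `Non-relapse`) harmonizes it. Passing
`--recipe session.json` to each command accumulates the provenance recipe;
`geotidy replay session.json raw_series.txt -o out/` reproduces every
export byte-identically, and `geotidy script session.json -o tidy_steps.py`
emits the equivalent commented Python script.

The same flow in Python:

```python
from geotidy import Session, parse_series_matrix, parse_platform_table

bundle = parse_series_matrix("demo/fixture_seed5_series_matrix.txt")
bundle.features = parse_platform_table("demo/fixture_seed5_platform.txt")
session = Session(bundle, outdir="out")
session.apply("split_key_value", column="characteristics_ch1",
              pattern={"text": ":", "mode": "literal"})
session.apply("attach_feature_ids", "assay", target_id_column="GENE_SYMBOL")
session.apply("summarize", "assay", stat="median")
session.apply("transpose", "assay")
session.apply("merge_tables", "merged", kind="inner")
session.export("merged", "tsv", "merged.tsv")
```

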