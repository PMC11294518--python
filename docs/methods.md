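# Methods

## Data model

A GEO series is held as a `SeriesBundle`: series-level metadata, a clinical
`AnnotationTable` keyed by sample accession (GSM), an optional numeric
`AssayMatrix` (features × samples, NaN for missing), and an optional feature
`AnnotationTable` keyed by probe identifier. One bundle always belongs to a
single platform; when a series spans several platforms, `select_platform`
returns the first listed unless an explicit GPL identifier is given.

Missing values are normalized at parse time: cells equal to `""`, `NA`,
`N/A`, `null`, or `--` (case-insensitive, whitespace-stripped) become
missing. The token set is a parameter of every parser because submitters
vary; the default covers the spellings that recur in GEO submissions.

Repeated sample-annotation keys — above all `!Sample_characteristics_ch1`,
which submitters reuse once per free-form variable — expand to suffixed
columns (`characteristics_ch1`, `characteristics_ch1.1`, …) in file order.
The same rule applies uniformly to any repeated key, including channel-2
(`_ch2`) lines, which are exposed as ordinary columns with no special
semantics: two-channel series are rare enough that merging channels is left
to explicit tidying operations. Non-numeric cells inside the assay block
are coerced to missing with a logged count rather than aborting the parse.

## Tidying operations

All operations are pure: the input table is never mutated, and the output
shares no state with it. Column operations preserve row count and order;
`filter_rows_by_value` preserves columns. Each operation appends exactly one
event to the session recipe.

Choices that the operation definitions leave open were resolved as follows:

- **Preset column filters.** `same_value` and `all_unique` evaluate over
  non-missing cells only; an entirely missing column qualifies as
  `same_value` (it is uninformative either way). The `dates` preset accepts
  a fixed dialect list (ISO 8601, `Mon DD YYYY`, `DD/MM/YYYY` or
  `MM/DD/YYYY`, `Month DD, YYYY`) kept as module-level data so it can be
  extended; `web_addresses` requires every non-missing cell to start with
  `http://`, `https://`, or `ftp://`. Selected presets combine
  disjunctively: a column is dropped if any one predicate holds.
- **shift_cells** moves (rather than copies) the first matching source cell
  per row, scanning the sources in the user-given order; later matches stay
  put. Blanking the source preserves the invariant that the multiset of
  non-missing values across sources plus target is unchanged — which makes
  the operation auditable. The copy-only alternative was rejected because it
  leaves duplicated values whose provenance is ambiguous.
- **split_key_value** trims whitespace around keys and values and compares
  keys case-sensitively (silently merging `Sex` and `sex` would hide a
  substitution the user should make deliberately). When all non-missing
  cells yield one key, the column is renamed to that key; heterogeneous
  keys expand the column in place into one column per distinct key, flagged
  `heterogeneous=true` in the recipe since that is an extension beyond the
  uniform case. A delimiter absent from every cell is a warning no-op.
- **split_column** names the parts `column_1..column_k`, `k` being the
  maximum part count over rows (optionally capped), pads short rows with
  missing, and trims whitespace. Rejoining the parts with the delimiter
  reconstructs every cell whenever the delimiter occurs in no part — a
  property the test suite checks over generated tables.
- **substitute** offers whole-cell literal replacement (idempotent whenever
  the replacement is outside the match set) and regex-substring rewriting;
  an invalid regex fails before any mutation.

Pattern arguments are literal (substring containment) or regular
expressions (`re.search` semantics) throughout.

## Assay summarization

`attach_feature_ids` keys each probe row with a platform column (gene
symbol, cytoband, …). Unmapped probes — absent from the platform table or
mapping to a missing cell — are dropped by default with a logged count;
`keep_under_sentinel` instead retains them grouped under their own probe
id. Dropping is the default because a gene-level matrix with anonymous
leftover rows is harder to reason about than an explicit count of what was
discarded. Multi-target mappings (`"A /// B"`) are not expanded
automatically; splitting the platform column first with the ordinary
tidying operations keeps that decision visible.

`summarize` collapses each group (order of first appearance) with mean,
median, min, or max over the group's non-missing values per sample; a
group-sample with no observed values stays missing. The median of an
even-sized group is the midpoint of the two central values. `keep_all`
relabels rows without collapsing, so duplicate identifiers are allowed —
and are rejected at transpose time, when they would have to become column
headers. Implementation-wise the collapse uses numpy's NaN-aware
reductions; the test suite checks it cell-for-cell against a naive
per-group loop built on the `statistics` module over randomized matrices up
to 200 × 20.

Row filtering accepts a sample column or a derived per-row statistic
(`row_mean`, `row_median`, `row_min`, `row_max`); the caller names the
column explicitly rather than the filter guessing a target.

## Merging and export

Joins require the assay in samples-by-features orientation and unique keys
on both sides. Row order is deterministic (left-side order, then unmatched
right-side keys in their original order) and name collisions get origin
suffixes `.clin` / `.assay`, so merged exports are byte-reproducible. Cell
values pass through without coercion.

Text exports are canonical: fixed column order, RFC-4180-style minimal
quoting, `\n` line endings, missing cells as empty fields (CSV/TSV) or
`null` (JSON). JSON cells that parse as numbers are emitted as numbers. The
BRB-ArrayTools export writes the paired-file layout its importer documents:
`<stem>_expression.txt` (tab-delimited, feature identifier first, one
column per array named by GSM) and `<stem>_covariates.txt` (header row of
covariate names, one row per array, array order matching the expression
columns).

## Provenance recipes

A `Recipe` is an ordered event log — operation name, parameters, table
role, resulting shape — plus a header with the series accession, a
timestamp, and a SHA-256 digest of the raw parsed input. Events store
parameters, never data values, so recipes stay small and shareable.
Serialization is canonical JSON (sorted keys), so equal recipes are
byte-identical documents. Replay verifies the input digest (overridable
with a warning; replay then completes or fails at the first inapplicable
event, never silently diverging) and re-applies the events in order; the
contract, enforced by tests, is that every exported file is byte-identical
to the original session's. `generate_script` renders the same events as a
standalone Python script — one commented block per event, parameters quoted
verbatim — whose outputs hash-equal the replay's. Timestamps live only in
the recipe header and never inside exported data files. The declarative
recipe, not the generated script, is the portable contract: it can be
validated, diffed, and re-rendered.

## Synthetic fixtures

The generator emulates the recurring pathologies of real series-matrix
files: key-value cells, multi-value cells, leftward-shifted annotations,
constant / unique / date / URL columns, vocabulary drift
("Relapse"/"Yes"), probe sets sharing a gene, and missing assay blocks.
Sample counts default to 6 (at least 2 are required — smaller series are
degenerate for tidying), features to 12, and assay values are drawn from a
log-normal-shaped distribution; the exact distribution is irrelevant to
correctness, only seed determinism matters, and the same spec plus seed
yields byte-identical files. Vocabulary pools (female/male,
Relapse/Non-relapse vs Yes/No, drug names) mirror the terms that real
submitters drift between, with a configurable drift rate (default 0.4).

Each fixture ships a ledger holding the clean clinical table and the
operation sequence that recovers it. The clean table is computed by a small
naive interpreter private to the fixtures module — simple set-cardinality
preset checks and literal splits, independent of the tidying
implementation — so the closed-loop tests (`tidy(pathological) == clean`)
genuinely compare two routes.

What the fixtures do **not** emulate: statistically realistic expression
values, real platform annotation vocabularies (chromosome positions, RefSeq
ids), multi-platform series files, quoting edge cases beyond GEO's standard
double-quoted dialect, and very large series. Passing tests therefore
demonstrate correctness of the transformations and the provenance
machinery, not robustness to every formatting accident in the wild archive.

## Profiling

A column is numeric when every non-missing cell parses as a number; numeric
columns are binned into uniform bins `[min + k·w, min + (k+1)·w)` with the
last bin closed (numpy histogram convention), defaulting to Sturges' rule
for the bin count when no width is given. Everything else gets category
counts sorted by descending count then name; mixed columns are conservative
and profile as categorical (or as `identifier` when all values are unique).
Counts plus missing always equal the row count. Rendering uses matplotlib's
Agg backend at 100 dpi, so requested pixel dimensions map directly to
figure size.

## Problem sizes and limitations

Test and acceptance runs use small problem sizes chosen to exercise every
code path — fixtures of 4–8 samples and ~12 features, oracle comparisons up
to 200 features × 20 samples, 100–200 generated cases per property — which
complete in seconds. The parser streams line-wise and the operations are
vectorized over pandas/numpy, so series in the thousands of samples are
well within reach, but nothing here is tuned for the largest series in the
archive. The network fetcher is plumbing only and untested against live
NCBI servers; recipes carry a schema version but no migration machinery
beyond a version check.
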