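# Methods

This note documents the data model, the import and exploration
procedures, the synthetic-data generator, and the numerical and design
choices behind pixelbase.

## Data model and its assumptions

The store is a relational schema around one central record, the Pixel
Set. Context entities — `Species`, `Strain`, `OmicsUnitType`,
`OmicsArea`, `OmicsUnit` — must exist *before* an import; submission
entities — `Experiment`, `Analysis`, `Pixeler`, `PixelSet`, `Pixel` —
are only ever created by the import workflow's final step.

Key modelling decisions:

* **Omics Unit identity is the triple (identifier, strain, unit type).**
  The same gene accession legitimately appears twice when a gene is
  measured both as an mRNA and as a protein, so the identifier alone
  cannot be a key. Units are scoped to the strain (not the species):
  strains of one species can differ in gene content, and the strain is
  part of the pre-registered context anyway.
* **Quality scores are unconstrained finite reals.** In practice they
  are p-values, but the field's contract is only "a quality score", so a
  value outside [0, 1] triggers a warning, not a rejection. Values and
  scores must be finite; NaN/inf are refused at the parsing boundary.
* **The store is append-only plus tag edits.** Deletion is not part of
  the catalog's job in v1; tags may be re-edited at any time because
  they are navigation aids, not provenance. The embedded engine is
  SQLite in a single file (`:memory:` for ephemeral use); a
  server-backed engine would be a configuration change, not a different
  code path.
* **The Pixeler is annotation, not authentication.** Who ran the
  analysis is recorded like any other metadata.

Referential integrity is enforced twice: by SQL foreign keys at write
time, and by `integrity_report()`, which re-walks every reference and
recounts pixels per set, for auditing stores modified out-of-band.

## Submission archives

A submission ZIP holds the metadata workbook (`meta.xlsx`), the
secondary-data file, the analysis notebook, and one or more Pixel Set
TSVs. Choices embodied in the format:

* **Checksums live in the workbook.** The workbook is the only
  annotation carrier in the bundle, so it declares one md5 per data
  file; `read_archive` recomputes and compares. The notebook and the
  secondary-data file are opaque blobs — only their checksums matter.
* **Named ranges, not cell coordinates.** Every scalar field of the
  workbook is addressed through a named range and the declarations table
  through a fixed sheet name, so the layout can evolve without breaking
  the parser. The template version is a literal string checked against a
  supported set, and the version gate runs before any field validation.
* **TSV dialect.** UTF-8, tab-separated, mandatory header
  `Omics Unit / Value / Quality score`, dot decimals with scientific
  notation accepted. Parsing is locale-independent: a comma decimal is a
  parse error, never silently interpreted.
* **Determinism.** Archives are written with fixed zip timestamps,
  sorted member order and pinned workbook document properties, so
  identical content produces identical bytes — which makes checksum and
  round-trip guarantees testable at the byte level.

## Import workflow

The submission lifecycle is a linear state machine: `created → uploaded
→ meta_checked → annotated → tagged → imported`, with the tag step
optional and any check failure terminating the session in `failed`.
The template-download step precedes the session: the template leaves the
system, so there is nothing to track until an upload happens.

Invariants:

* **Nothing is written before the final step.** Meta checks (checksum
  verification, version gate, resolution of every Omics Unit in every
  Pixel Set file) and annotation confirmation only read the store.
* **The final import is atomic.** Experiment, analysis, pixeler, pixel
  sets, pixels and tags are persisted in a single transaction; any
  failure rolls back to a byte-identical store (asserted via a canonical
  content digest in tests). A fault-injection hook exercises mid-
  transaction failures.
* **Checksum mismatches are reported before parse errors**: a tampered
  file fails as an integrity problem, not as a confusing syntax error.
* **Re-importing an identical archive creates new Pixel Sets.** There is
  no content-based deduplication: the catalog records analyses as
  submitted, and silent merging would hide provenance.
* Tags declared in the workbook and tags given at the tag step are
  unioned onto every created Pixel Set.
* A calling sequence violating the state order raises a precondition
  error without changing session state; a failed session is terminal.

## Exploration semantics

* Facets (species, unit types, areas, tags) combine with **AND**; values
  within one facet with **OR**. An all-empty filter matches everything,
  and adding a facet can only shrink the result set (tested against an
  exhaustive predicate scan).
* **Tags are hierarchical** `/`-separated paths compared
  case-insensitively; filtering on a tag includes its descendants
  (prefix-of-segments containment, the usual semantics for hierarchical
  labels).
* **Keyword search is case-insensitive plain substring** over the
  analysis and experiment descriptions, and likewise for Omics Unit
  description filtering. No stemming, no regular expressions: the
  intended queries are literal tokens such as a method name or a GO-like
  annotation word, and substring matching keeps the behaviour
  predictable.
* A set's species and unit-type facets are derived from its Pixels'
  units rather than stored denormalized, so they can never disagree with
  the data.
* Summaries use **20 equal-width histogram bins over the observed
  range** — deterministic given the data; single-valued data fall into
  the first bin; an empty set reports undefined means via a flag rather
  than NaN.

## Export

The multi-omics table joins per-set Pixel lists on (identifier, strain):
units measured under different unit types join on their shared gene
identifier, which is exactly what makes an mRNA/protein comparison one
table. `intersection` (default) keeps units present in every set,
`union` keeps all with empty cells for gaps. Joining across species is
refused — identifiers from different organisms are not comparable keys.
Rows are sorted by identifier; values are serialized with a
shortest-round-trip decimal representation (scientific notation below
1e-3), so every written cell equals the stored float exactly and
`write_table → read_table` is cell-exact.

## Synthetic data generator

`generate_instance` emulates the structure of a two-layer multi-omics
study: one organism and strain, two omics areas (RNA sequencing, mass
spectrometry) with matching unit types, `n_units` registered Omics Units
shared between `n_pixel_sets` Pixel Sets, one submission archive per
omics area in use.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_units` | 100 | enough rows for distribution checks, desk-scale runtime |
| `n_pixel_sets` | 2 | the canonical transcriptome-vs-proteome comparison |
| `value_model` | normal(0, 1) | log2 fold changes are roughly symmetric around 0 |
| `qs_model` | uniform(0, 1) | p-values under a global null are uniform |
| `overlap_fraction` | 0.5 | proteomics typically covers a fraction of the transcriptome, so partial overlap is the realistic default |
| `keyword_fraction` | 0.1 | a functional keyword annotates a minority of genes |

Exactly `round(keyword_fraction × n_units)` unit descriptions contain
the keyword (assuming the keyword does not occur in the generator's
fixed description templates); quality scores are clipped to [0, 1].
All randomness flows from one `numpy` generator seeded by `seed`, and
archive bytes are deterministic.

What the generator does **not** emulate: correlated values between
omics layers, signal/null mixtures in the p-values, realistic annotation
text, multiple species or strains, or primary-data artefacts. Passing
tests therefore demonstrate the catalog's bookkeeping — validation,
atomicity, query and join correctness — not anything about biological
signal recovery.

The worked example (`case_study_fixture`) is not sampled: it packages
the five-gene alkaline-pH excerpt with its published log2 fold changes,
p-values and gene descriptions verbatim, under the tags
`Candida glabrata / alkaline pH / WT / logFC`.

## Numerical and degenerate-input choices

* Number serialization must round-trip: the shortest decimal whose
  `float()` equals the stored value, switching to scientific notation
  below 1e-3.
* md5 is used for file checksums — an integrity check against accidental
  corruption, matching common submission-pipeline practice; it is not a
  security boundary.
* Empty Pixel Set TSVs (header only) are valid and yield empty sets;
  empty selections and empty keywords in pixel filtering are errors.
* Case-insensitivity is implemented with `str.casefold` throughout
  (names, tags, keywords).

## Problem sizes used in the checks

The test suite and the acceptance script run on the five-gene worked
example plus synthetic instances of 4–40 units and 1–6 Pixel Sets
(50 random stores for the filter-equivalence scan, 100 corruption or
fault-injection scenarios for atomicity, every byte position of the
worked example's declared files for checksum soundness, and 10,000 units
for the quality-score calibration check). These sizes exercise every
code path while keeping a full run in the tens of seconds.

## Known limitations

* No deletion or in-place repair of failed sessions; start a new
  session.
* The optional full-scale replication (5,253- and 1,879-pixel sets)
  requires the original submission archives, which are not bundled; the
  corresponding check runs only when they are provided locally.
* The query layer filters in Python after loading candidate sets, which
  is appropriate for catalog-scale stores (thousands of Pixel Sets), not
  for warehouse-scale ones.
* Concurrent writers are not coordinated beyond SQLite's own locking.
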