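# pixelbase

An embeddable catalog for quantitative **secondary omics data**: annotate,
store, explore and export *Pixel Sets* from a Python library or a command
line, backed by a single-file SQLite database.

## The problem

Multi-omics projects accumulate the results of many secondary-data
analyses: per-gene log2 fold changes from an RNA-seq differential
analysis, per-protein abundance ratios from mass spectrometry, and so on.
Each such result is a set of measurements — here called **Pixels**: one
value plus one quality score (typically the p-value of the differential
test) bound to one registered cellular component, the **Omics Unit**
(an mRNA, a protein, a genomic region…). The **Pixel Set**, the
collection of Pixels produced by one analysis, is the central record.

pixelbase keeps these results findable and comparable:

* **Pre-registration** of the annotation context — species, strain, omics
  unit type (mRNA / protein / …), omics area (RNA sequencing / mass
  spectrometry / …) and every Omics Unit with a description and a
  reference-database link — before anything can be imported.
* **Submission archives**: a ZIP bundling a metadata workbook (xlsx),
  the secondary-data file, the analysis notebook, and one or more Pixel
  Set TSVs (`Omics Unit`, `Value`, `Quality score`), with an md5
  checksum declared per data file.
* A **six-step import workflow** (template download → upload → automatic
  meta checks → annotation confirmation → optional tags → import) that
  verifies checksums, the template version and the pre-registration of
  every Omics Unit before anything is written, and persists the final
  import in one atomic transaction.
* **Exploration**: faceted filtering (AND across facets, OR within one),
  hierarchical tags with descendant matching, free keyword search over
  analysis/experiment descriptions, per-set value/quality-score
  summaries, and keyword filtering of Pixels by their unit description.
* **Cross-omics export**: an intersection or union join of several Pixel
  Sets keyed by Omics Unit identifier within one strain, written as TSV
  with values exactly as stored.

Statistical analysis is deliberately out of scope: pixelbase manages the
results of analyses, it does not produce them.

## Worked example

The packaged worked example is a five-gene excerpt of an alkaline-pH
stress study in the pathogenic yeast *Candida glabrata*: Pixel Set A
holds transcriptomic log2 fold changes (RNA sequencing, mRNA), Pixel Set
B proteomic ones (mass spectrometry, protein), both tagged
`Candida glabrata`, `alkaline pH`, `WT`, `logFC`.

```python
import pixelbase as pb

store, archive_a, archive_b = pb.case_study_fixture()
pb.run_import(store, archive_a)   # ImportResult(pixel_sets_created=1, pixels_created=5, ...)
pb.run_import(store, archive_b)   # ImportResult(pixel_sets_created=1, pixels_created=5, ...)

sets = pb.filter_pixelsets(
    store, pb.FilterSpec.build(tags={"Candida glabrata", "alkaline pH"})
)
len(sets)                         # 2 — both Pixel Sets found by their tags

table = pb.export_selection(
    store, pb.Selection(sets), "intersection", unit_keyword="pathogenesis"
)
print(pb.write_table(table).decode())
```

which prints (description column elided here):

```
Omics unit    Pixel_Set_A.txt:value  Pixel_Set_A.txt:qs  Pixel_Set_B.txt:value  Pixel_Set_B.txt:qs
CAGL0F04807g  1.09                   2.23e-19            1.81                   7.31e-05
CAGL0F06457g  0.3                    0.0414              0.19                   0.265
CAGL0I02970g  0.9                    4.65e-16            -2.64                  2.19e-05
CAGL0I10516g  1.5                    8.29e-60            0.57                   0.0116
CAGL0L08448g  1.67                   1.77e-75            -0.57                  0.00704
```

Five genes annotated with "pathogenesis" were measured at both the mRNA
and the protein level. Three (CAGL0F04807g, CAGL0F06457g, CAGL0I10516g)
are coherently induced in both omics layers; two (CAGL0I02970g,
CAGL0L08448g) show opposite signs — induced as transcripts, repressed as
proteins — the kind of discordance that flags post-transcriptional
regulation or measurement noise for follow-up.

The same run from the shell:

```bash
pixelbase --store demo.db fixtures case-study -o fx
pixelbase --store demo.db import fx/case_study_A.zip --yes   # needs context registered first;
pixelbase --store demo.db query --tag "Candida glabrata" --tag "alkaline pH"
pixelbase --store demo.db export --tag "Candida glabrata" \
    --unit-keyword pathogenesis --join intersection -o table.tsv
```

(`pixelbase register …` subcommands create the species/strain/type/area
context and bulk-register Omics Units from a TSV; see `pixelbase --help`.)

## Synthetic data

`pixelbase.generate_instance(FixtureParams(...))` builds seeded synthetic
studies — a pre-registered store plus submission archives that pass the
full import workflow — with controllable unit counts, keyword fraction in
unit descriptions, unit overlap between sets, and value/quality-score
distributions. Identical parameters and seed give byte-identical
archives. `corrupt_archive` deterministically damages an archive
(byte flip, dropped member, altered template version) for negative-path
testing.

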