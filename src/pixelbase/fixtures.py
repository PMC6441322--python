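"""Synthetic stores and submission archives, plus the packaged worked example.

Two generators:

* :func:`generate_instance` builds a seeded synthetic study: a store with
  pre-registered context (one organism, two omics areas) and submission
  archives that pass the full import workflow. It controls the fraction
  of Omics Unit descriptions carrying a target keyword, the unit overlap
  between sets, and the value/quality-score distributions (log-fold-
  change-like values, p-value-like scores). Same parameters + seed ⇒
  byte-identical archives.

* :func:`case_study_fixture` builds the worked example: two Pixel Sets
  over five Candida glabrata genes — a transcriptomic (RNA sequencing,
  mRNA) and a proteomic (mass spectrometry, protein) log2-fold-change
  set from an alkaline pH-shift comparison, with the published values,
  p-values and gene descriptions.

:func:`corrupt_archive` deterministically damages an archive for
negative-path testing of the import checks.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .archive import (
    AnalysisMeta,
    ExperimentMeta,
    FileRef,
    PixelerMeta,
    PixelRecord,
    PixelSetDeclaration,
    SubmissionMeta,
    WORKBOOK_MEMBER,
    build_workbook,
    deterministic_zip,
    md5_hex,
    parse_workbook,
    write_archive,
    write_pixelset_file,
    _zip_members,
)
from .errors import ValidationError
from .store import PixelStore

# ------------------------------------------------------------------ #
# worked example: 5 C. glabrata genes measured at the mRNA (set A,
# RNA sequencing) and protein (set B, mass spectrometry) levels after
# an alkaline pH shift. Values are log2 fold changes, quality scores
# the p-values of the differential analyses. Every description
# contains the keyword "pathogenesis".

CASE_STUDY_GENES: tuple[tuple[str, str, float, float, float, float], ...] = (
    (
        "CAGL0F04807g",
        "Ortholog(s) have role in pathogenesis and cell surface, hyphal cell wall, "
        "integral component of mitochondrial outer membrane, plasma membrane "
        "localization",
        1.09, 2.23e-19, 1.81, 7.31e-5,
    ),
    (
        "CAGL0F06457g",
        "Ortholog(s) have role in fungal-type cell wall organization or biogenesis, "
        "mitochondrial outer membrane translocase complex assembly, pathogenesis, "
        "phospholipid transport, protein import into mitochondrial outer membrane",
        0.30, 4.14e-2, 0.19, 2.65e-1,
    ),
    (
        "CAGL0I02970g",
        "Ortholog(s) have delta14-sterol reductase activity and role in cellular "
        "response to drug, ergosterol biosynthetic process, filamentous growth of a "
        "population of unicellular organisms in response to biotic stimulus, "
        "pathogenesis",
        0.90, 4.65e-16, -2.64, 2.19e-5,
    ),
    (
        "CAGL0I10516g",
        "Ortholog(s) have role in fungal-type cell wall organization, pathogenesis "
        "and cytoplasm, eisosome, integral component of plasma membrane, membrane "
        "raft localization",
        1.50, 8.29e-60, 0.57, 1.16e-2,
    ),
    (
        "CAGL0L08448g",
        "Ortholog(s) have role in actin cytoskeleton organization, eisosome "
        "assembly, negative regulation of protein phosphorylation, negative "
        "regulation of sphingolipid biosynthetic process and pathogenesis",
        1.67, 1.77e-75, -0.57, 7.04e-3,
    ),
)

CASE_STUDY_TAGS = ("Candida glabrata", "alkaline pH", "WT", "logFC")

_CGD_URL = "http://www.candidagenome.org/cgi-bin/locus.pl?locus={gene}&organism=C_glabrata_CBS138"


def case_study_fixture() -> tuple[PixelStore, bytes, bytes]:
    """The packaged worked example: (pre-registered store, archive A, archive B)."""
    store = PixelStore()
    species = store.register_species(
        "Candida glabrata", "pathogenic yeast", "http://www.candidagenome.org/"
    )
    strain = store.register_strain("ATCC2001", species)
    mrna = store.register_omics_unit_type("mRNA", "messenger RNA abundance")
    protein = store.register_omics_unit_type("protein", "protein abundance")
    store.register_omics_area("RNA sequencing", "high-throughput cDNA sequencing")
    store.register_omics_area("Mass spectrometry", "HT protein identification/quantification")

    for gene, description, *_ in CASE_STUDY_GENES:
        for ut in (mrna, protein):
            store.register_omics_unit(
                gene, description, _CGD_URL.format(gene=gene), strain, ut
            )

    def records(value_col: int, qs_col: int) -> list[PixelRecord]:
        return [
            PixelRecord(g[0], g[value_col], g[qs_col]) for g in CASE_STUDY_GENES
        ]

    archive_a = _case_archive(
        label="A",
        area="RNA sequencing",
        unit_type="mRNA",
        experiment_desc=(
            "RNA sequencing of Candida glabrata wild type cells during an alkaline "
            "pH shift, compared to standard growth conditions"
        ),
        analysis_desc=(
            "Differential expression analysis of log2 fold changes (LIMMA) between "
            "alkaline pH and control cultures; secondary data are per-gene counts"
        ),
        records=records(2, 3),
    )
    archive_b = _case_archive(
        label="B",
        area="Mass spectrometry",
        unit_type="protein",
        experiment_desc=(
            "Mass spectrometry quantification of the Candida glabrata wild type "
            "proteome during an alkaline pH shift versus standard growth"
        ),
        analysis_desc=(
            "Differential abundance analysis of log2 fold changes between alkaline "
            "pH and control samples; secondary data are protein abundances"
        ),
        records=records(4, 5),
    )
    return store, archive_a, archive_b


def _case_archive(label, area, unit_type, experiment_desc, analysis_desc, records):
    pixel_file = f"Pixel_Set_{label}.txt"
    secondary = f"secondary_data_{label}.tsv"
    notebook = f"notebook_{label}.Rmd"
    files = {
        pixel_file: write_pixelset_file(records),
        secondary: _fake_secondary_data(records),
        notebook: _fake_notebook(analysis_desc),
    }
    meta = SubmissionMeta(
        experiment=ExperimentMeta(
            description=experiment_desc,
            omics_area_name=area,
            completed_at="2018-06-01",
            released_at="2019-03-27",
        ),
        analysis=AnalysisMeta(
            description=analysis_desc,
            secondary_data=FileRef(secondary, "0" * 32),
            notebook=FileRef(notebook, "0" * 32),
            completed_at="2018-07-01",
        ),
        pixeler=PixelerMeta(name="Case-study pixeler", contact="pixeler@example.org"),
        declarations=(
            PixelSetDeclaration(
                filename=pixel_file,
                md5="0" * 32,  # recomputed by write_archive
                omics_unit_type_name=unit_type,
                strain_name="ATCC2001",
                species_name="Candida glabrata",
                description=f"Pixel Set {label} of the alkaline pH case study",
                tags=CASE_STUDY_TAGS,
            ),
        ),
    )
    return write_archive(meta, files)


def _fake_secondary_data(records: list[PixelRecord]) -> bytes:
    lines = ["id\tcondition_1\tcondition_2"]
    for i, r in enumerate(records):
        lines.append(f"{r.omics_unit_identifier}\t{100 + 7 * i}\t{90 + 11 * i}")
    return ("\n".join(lines) + "\n").encode()


def _fake_notebook(analysis_desc: str) -> bytes:
    return (
        "---\ntitle: secondary data analysis\n---\n\n"
        f"{analysis_desc}\n\n```r\n# analysis code lives here\n```\n"
    ).encode()


# ------------------------------------------------------------------ #
# parametric generator

_VALUE_FAMILIES = ("normal", "uniform", "laplace")
_QS_FAMILIES = ("uniform", "beta")


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of a synthetic study.

    ``n_units`` registered Omics Units are shared between
    ``n_pixel_sets`` Pixel Sets: a fraction ``overlap_fraction`` of them
    appears in every set, the remainder is split between sets. Exactly
    ``round(keyword_fraction * n_units)`` unit descriptions contain
    ``keyword``. Values follow ``value_model`` (family, location, scale)
    on the log2 scale; quality scores follow ``qs_model`` over [0, 1].
    """

    n_units: int = 100
    n_pixel_sets: int = 2
    keyword: str = "pathogenesis"
    keyword_fraction: float = 0.1
    value_model: tuple[str, float, float] = ("normal", 0.0, 1.0)
    qs_model: tuple[str, float, float] = ("uniform", 0.0, 1.0)
    overlap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 1:
            raise ValidationError("n_units must be >= 1")
        if self.n_pixel_sets < 1:
            raise ValidationError("n_pixel_sets must be >= 1")
        for name, frac in (("keyword_fraction", self.keyword_fraction),
                           ("overlap_fraction", self.overlap_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {frac}")
        if self.value_model[0] not in _VALUE_FAMILIES:
            raise ValidationError(f"value_model family must be one of {_VALUE_FAMILIES}")
        if self.qs_model[0] not in _QS_FAMILIES:
            raise ValidationError(f"qs_model family must be one of {_QS_FAMILIES}")


def _draw_values(rng: np.random.Generator, model, n: int) -> np.ndarray:
    family, a, b = model
    if family == "normal":
        return rng.normal(a, b, size=n)
    if family == "laplace":
        return rng.laplace(a, b, size=n)
    return rng.uniform(a, b, size=n)


def _draw_scores(rng: np.random.Generator, model, n: int) -> np.ndarray:
    family, a, b = model
    if family == "beta":
        return rng.beta(a, b, size=n)
    return rng.uniform(a, b, size=n)


def generate_instance(params: FixtureParams) -> tuple[PixelStore, list[bytes]]:
    """Build (pre-registered store, submission archives) for ``params``.

    The archives are not yet imported; feeding them through
    :func:`pixelbase.workflow.run_import` against the returned store
    succeeds by construction. Identical params give identical bytes.
    """
    rng = np.random.default_rng(params.seed)
    store = PixelStore()
    species = store.register_species(
        "Synthetica exemplaris", "synthetic organism for generated fixtures"
    )
    strain = store.register_strain("SYN-1", species)
    types = [
        store.register_omics_unit_type("mRNA", "messenger RNA abundance"),
        store.register_omics_unit_type("protein", "protein abundance"),
    ]
    areas = ["RNA sequencing", "Mass spectrometry"]
    for area in areas:
        store.register_omics_area(area, f"synthetic {area} experiments")

    idents = [f"SYN0x{i:05d}g" for i in range(params.n_units)]
    n_kw = round(params.keyword_fraction * params.n_units)
    kw_idx = set(rng.choice(params.n_units, size=n_kw, replace=False).tolist())
    descriptions = {}
    for i, ident in enumerate(idents):
        if i in kw_idx:
            descriptions[ident] = (
                f"synthetic gene product {ident} with role in {params.keyword}"
            )
        else:
            descriptions[ident] = f"uncharacterized synthetic gene product {ident}"
        for ut in types:
            store.register_omics_unit(
                ident, descriptions[ident],
                f"https://example.org/units/{ident}", strain, ut,
            )

    # unit membership: shared prefix + per-set slice of the remainder
    n_shared = round(params.overlap_fraction * params.n_units)
    shared, rest = idents[:n_shared], idents[n_shared:]
    memberships = [
        shared + rest[i:: params.n_pixel_sets] for i in range(params.n_pixel_sets)
    ]

    # group sets by omics area (one experiment/archive per area in use)
    by_area: dict[str, list[int]] = {}
    for i in range(params.n_pixel_sets):
        by_area.setdefault(areas[i % len(areas)], []).append(i)

    archives = []
    for area, set_indices in by_area.items():
        files: dict[str, bytes] = {}
        declarations = []
        for i in set_indices:
            members = sorted(memberships[i])
            values = _draw_values(rng, params.value_model, len(members))
            scores = np.clip(
                _draw_scores(rng, params.qs_model, len(members)), 0.0, 1.0
            )
            records = [
                PixelRecord(ident, float(v), float(q))
                for ident, v, q in zip(members, values, scores)
            ]
            filename = f"pixel_set_{i + 1}.txt"
            files[filename] = write_pixelset_file(records)
            declarations.append(
                PixelSetDeclaration(
                    filename=filename,
                    md5="0" * 32,
                    omics_unit_type_name=types[i % len(types)].name,
                    strain_name=strain.name,
                    species_name=species.name,
                    description=f"synthetic pixel set {i + 1} ({area})",
                    tags=("synthetic", f"set-{i + 1}"),
                )
            )
        label = area.replace(" ", "_")
        secondary = f"secondary_data_{label}.tsv"
        notebook = f"notebook_{label}.Rmd"
        files[secondary] = _fake_secondary_data(
            [PixelRecord(i, 0.0, 0.0) for i in idents[:5]]
        )
        files[notebook] = _fake_notebook(f"synthetic analysis for {area}")
        meta = SubmissionMeta(
            experiment=ExperimentMeta(
                description=f"synthetic {area} experiment (seed {params.seed})",
                omics_area_name=area,
                completed_at="2020-01-01",
            ),
            analysis=AnalysisMeta(
                description=f"synthetic differential analysis for {area}",
                secondary_data=FileRef(secondary, "0" * 32),
                notebook=FileRef(notebook, "0" * 32),
                completed_at="2020-01-02",
            ),
            pixeler=PixelerMeta(name="Fixture generator"),
            declarations=tuple(declarations),
        )
        archives.append(write_archive(meta, files))
    return store, archives


# ------------------------------------------------------------------ #
# deterministic corruption

CORRUPTION_MODES = ("flip_byte", "drop_member", "alter_version")


def corrupt_archive(zip_bytes: bytes, mode: str, seed: int = 0) -> bytes:
    """Damage an archive deterministically for negative-path tests.

    ``flip_byte`` flips one byte of a declared Pixel Set file (checksum
    mismatch), ``drop_member`` removes a declared member, and
    ``alter_version`` rewrites the workbook's template version to an
    unsupported string.
    """
    members = _zip_members(zip_bytes)
    meta = parse_workbook(members[WORKBOOK_MEMBER])
    rng = np.random.default_rng(seed)

    if mode == "flip_byte":
        decls = meta.declarations
        target = decls[int(rng.integers(len(decls)))].filename
        data = bytearray(members[target])
        pos = int(rng.integers(len(data)))
        data[pos] ^= 0x01
        members[target] = bytes(data)
        return deterministic_zip(members)
    if mode == "drop_member":
        refs = meta.declared_files()
        target = refs[int(rng.integers(len(refs)))].filename
        del members[target]
        return deterministic_zip(members)
    if mode == "alter_version":
        from openpyxl import load_workbook

        wb = load_workbook(io.BytesIO(members[WORKBOOK_MEMBER]))
        (sheet, coord), = wb.defined_names["template_version"].destinations
        wb[sheet][coord] = "0.0-unsupported"
        buf = io.BytesIO()
        wb.save(buf)
        members[WORKBOOK_MEMBER] = deterministic_zip(_zip_members(buf.getvalue()))
        return deterministic_zip(members)
    raise ValidationError(f"unknown corruption mode {mode!r}; use one of {CORRUPTION_MODES}")


def write_fixture_dir(zip_bytes: bytes, path: str | Path) -> None:
    """Unpack an archive into a plain directory for debugging."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(io.BytesIO(zip_bytes)) as zf:
        zf.extractall(path)
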