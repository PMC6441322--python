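"""Submission-archive I/O.

A submission is a ZIP bundle holding:

* ``meta.xlsx`` — the metadata workbook (Office Open XML) describing the
  experiment, the analysis, the pixeler and one declaration per bundled
  Pixel Set file, including an md5 checksum for every data file;
* the secondary-data file (TSV, opaque beyond its checksum);
* the analysis notebook (opaque blob, e.g. R Markdown or Jupyter);
* one or more Pixel Set files (TSV: Omics Unit id, value, quality score).

The workbook layout is addressed through named ranges (one per scalar
field) plus a fixed-name declarations sheet, so cells can move between
template revisions without breaking the parser. Scalar fields live on the
"Submission" sheet, declarations on "Pixel datasets", and the
pre-registration choice lists (species, strains, unit types, areas known
to a store) on "Choices".

All archives written here are byte-deterministic: member order, zip
timestamps and workbook document properties are fixed, so identical
content yields identical bytes.
"""

from __future__ import annotations

import datetime
import hashlib
import io
import math
import re
import warnings
import zipfile
from dataclasses import dataclass, field, replace

from openpyxl import Workbook, load_workbook
from openpyxl.utils import absolute_coordinate, quote_sheetname
from openpyxl.workbook.defined_name import DefinedName

from .errors import ArchiveError, FormatError, ParseError, ValidationError, VersionError
from .models import FileRef, TagPath

TEMPLATE_VERSION = "1.0"
SUPPORTED_TEMPLATE_VERSIONS = frozenset({"1.0"})

WORKBOOK_MEMBER = "meta.xlsx"

#: Mandatory header of a Pixel Set TSV file.
PIXELSET_HEADER = ("Omics Unit", "Value", "Quality score")

_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp for determinism
_DOC_DATE = datetime.datetime(2019, 1, 1)


# --------------------------------------------------------------------- #
# number formatting (shared with the export writer)

def format_number(x: float) -> str:
    """Render a float with dot decimals; scientific notation below 1e-3.

    The representation always round-trips through :func:`float`, and is
    the shortest that does so, so written values equal stored values
    exactly.
    """
    x = float(x)
    if x == 0:
        return "0"
    if abs(x) < 1e-3:
        for prec in range(17):
            s = f"{x:.{prec}e}"
            if float(s) == x:
                return s
    return repr(x)


# --------------------------------------------------------------------- #
# metadata model

@dataclass(frozen=True)
class ExperimentMeta:
    description: str = ""
    omics_area_name: str = ""
    completed_at: str = ""
    released_at: str = ""


@dataclass(frozen=True)
class AnalysisMeta:
    description: str = ""
    secondary_data: FileRef | None = None
    notebook: FileRef | None = None
    completed_at: str = ""


@dataclass(frozen=True)
class PixelerMeta:
    name: str = ""
    contact: str = ""


@dataclass(frozen=True)
class PixelSetDeclaration:
    """One row of the "Pixel datasets" sheet: a bundled Pixel Set file."""

    filename: str
    md5: str
    omics_unit_type_name: str
    strain_name: str
    species_name: str
    description: str = ""
    tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SubmissionMeta:
    experiment: ExperimentMeta = ExperimentMeta()
    analysis: AnalysisMeta = AnalysisMeta()
    pixeler: PixelerMeta = PixelerMeta()
    declarations: tuple[PixelSetDeclaration, ...] = ()
    template_version: str = TEMPLATE_VERSION

    def declared_files(self) -> list[FileRef]:
        """Every (filename, md5) pair the workbook commits to."""
        refs = []
        if self.analysis.secondary_data:
            refs.append(self.analysis.secondary_data)
        if self.analysis.notebook:
            refs.append(self.analysis.notebook)
        refs.extend(FileRef(d.filename, d.md5) for d in self.declarations)
        return refs


@dataclass(frozen=True)
class PixelRecord:
    """One parsed row of a Pixel Set file."""

    omics_unit_identifier: str
    value: float
    quality_score: float


@dataclass(frozen=True)
class ChecksumEntry:
    filename: str
    declared: str
    computed: str

    @property
    def match(self) -> bool:
        return self.declared == self.computed


@dataclass(frozen=True)
class ArchiveBundle:
    meta: SubmissionMeta
    files: dict[str, bytes]
    checksum_report: tuple[ChecksumEntry, ...]

    def checksum_mismatches(self) -> list[ChecksumEntry]:
        return [e for e in self.checksum_report if not e.match]


# --------------------------------------------------------------------- #
# deterministic zip

def deterministic_zip(members: dict[str, bytes]) -> bytes:
    """Pack members (sorted by name, fixed timestamps) into ZIP bytes."""
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):
            info = zipfile.ZipInfo(name, date_time=_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, members[name])
    return buf.getvalue()


def _zip_members(data: bytes) -> dict[str, bytes]:
    try:
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            return {name: zf.read(name) for name in zf.namelist()}
    except zipfile.BadZipFile as exc:
        raise ArchiveError(f"not a readable ZIP archive: {exc}") from exc


# --------------------------------------------------------------------- #
# workbook writing

_SCALAR_FIELDS = {
    # named range -> (row, label)
    "template_version": (1, "Template version"),
    "experiment_description": (3, "Experiment: description"),
    "experiment_omics_area": (4, "Experiment: omics area"),
    "experiment_completed_at": (5, "Experiment: completed (YYYY-MM-DD)"),
    "experiment_released_at": (6, "Experiment: released (YYYY-MM-DD)"),
    "analysis_description": (8, "Analysis: description"),
    "analysis_completed_at": (9, "Analysis: completed (YYYY-MM-DD)"),
    "secondary_data_filename": (10, "Analysis: secondary data file"),
    "secondary_data_md5": (11, "Analysis: secondary data md5"),
    "notebook_filename": (12, "Analysis: notebook file"),
    "notebook_md5": (13, "Analysis: notebook md5"),
    "pixeler_name": (15, "Pixeler: name"),
    "pixeler_contact": (16, "Pixeler: contact"),
}

_DECL_HEADER = (
    "Filename", "MD5 checksum", "Omics unit type", "Strain", "Species",
    "Description", "Tags",
)

_CHOICE_COLUMNS = ("Species", "Strain", "Omics unit type", "Omics area")


def build_workbook(
    meta: SubmissionMeta | None = None,
    choices: dict[str, list[str]] | None = None,
) -> bytes:
    """Write the metadata workbook; ``meta=None`` yields a blank template."""
    meta = meta or SubmissionMeta()
    choices = choices or {}
    wb = Workbook()
    wb.properties.created = _DOC_DATE
    wb.properties.modified = _DOC_DATE

    ws = wb.active
    ws.title = "Submission"
    values = {
        "template_version": meta.template_version,
        "experiment_description": meta.experiment.description,
        "experiment_omics_area": meta.experiment.omics_area_name,
        "experiment_completed_at": meta.experiment.completed_at,
        "experiment_released_at": meta.experiment.released_at,
        "analysis_description": meta.analysis.description,
        "analysis_completed_at": meta.analysis.completed_at,
        "secondary_data_filename": meta.analysis.secondary_data.filename
        if meta.analysis.secondary_data else "",
        "secondary_data_md5": meta.analysis.secondary_data.md5
        if meta.analysis.secondary_data else "",
        "notebook_filename": meta.analysis.notebook.filename
        if meta.analysis.notebook else "",
        "notebook_md5": meta.analysis.notebook.md5 if meta.analysis.notebook else "",
        "pixeler_name": meta.pixeler.name,
        "pixeler_contact": meta.pixeler.contact,
    }
    for name, (row, label) in _SCALAR_FIELDS.items():
        ws.cell(row=row, column=1, value=label)
        ws.cell(row=row, column=2, value=values[name])
        ref = f"{quote_sheetname(ws.title)}!{absolute_coordinate(f'B{row}')}"
        wb.defined_names.add(DefinedName(name, attr_text=ref))

    decl = wb.create_sheet("Pixel datasets")
    for col, label in enumerate(_DECL_HEADER, start=1):
        decl.cell(row=1, column=col, value=label)
    for r, d in enumerate(meta.declarations, start=2):
        row = (d.filename, d.md5, d.omics_unit_type_name, d.strain_name,
               d.species_name, d.description, ",".join(d.tags))
        for col, value in enumerate(row, start=1):
            decl.cell(row=r, column=col, value=value)

    ch = wb.create_sheet("Choices")
    lists = {
        "Species": choices.get("species", []),
        "Strain": choices.get("strains", []),
        "Omics unit type": choices.get("unit_types", []),
        "Omics area": choices.get("omics_areas", []),
    }
    for col, label in enumerate(_CHOICE_COLUMNS, start=1):
        ch.cell(row=1, column=col, value=label)
        for r, name in enumerate(lists[label], start=2):
            ch.cell(row=r, column=col, value=name)

    buf = io.BytesIO()
    wb.save(buf)
    # openpyxl stamps save time into the inner zip and the core properties;
    # pin both so identical content yields identical bytes
    members = _zip_members(buf.getvalue())
    core = "docProps/core.xml"
    if core in members:
        members[core] = re.sub(
            rb"(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)",
            rb"\g<1>2019-01-01T00:00:00Z\g<2>",
            members[core],
        )
    return deterministic_zip(members)


def generate_template(store) -> bytes:
    """Blank submission workbook pre-filled with the store's choice lists."""
    return build_workbook(
        meta=None,
        choices={
            "species": store.species_names(),
            "strains": store.strain_names(),
            "unit_types": store.unit_type_names(),
            "omics_areas": store.omics_area_names(),
        },
    )


# --------------------------------------------------------------------- #
# workbook parsing

def _named_value(wb, name: str) -> str:
    try:
        defn = wb.defined_names[name]
    except KeyError:
        raise FormatError(f"workbook lacks the named range {name!r}") from None
    (sheet, coord), = defn.destinations
    value = wb[sheet][coord].value
    return "" if value is None else str(value).strip()


def read_choice_lists(workbook_bytes: bytes) -> dict[str, list[str]]:
    """Choice lists of a template, keyed like ``generate_template`` input."""
    wb = _load(workbook_bytes)
    ws = wb["Choices"]
    out: dict[str, list[str]] = {}
    keys = {"Species": "species", "Strain": "strains",
            "Omics unit type": "unit_types", "Omics area": "omics_areas"}
    for col, label in enumerate(_CHOICE_COLUMNS, start=1):
        names = []
        for row in range(2, ws.max_row + 1):
            v = ws.cell(row=row, column=col).value
            if v not in (None, ""):
                names.append(str(v))
        out[keys[label]] = names
    return out


def _load(workbook_bytes: bytes):
    try:
        return load_workbook(io.BytesIO(workbook_bytes), data_only=True)
    except Exception as exc:  # openpyxl raises various things on garbage
        raise FormatError(f"not a readable workbook: {exc}") from exc


def parse_workbook(workbook_bytes: bytes) -> SubmissionMeta:
    """Extract a :class:`SubmissionMeta`; the version gate runs first."""
    wb = _load(workbook_bytes)
    version = _named_value(wb, "template_version")
    if version not in SUPPORTED_TEMPLATE_VERSIONS:
        raise VersionError(
            f"unsupported template version {version!r}"
            f" (supported: {sorted(SUPPORTED_TEMPLATE_VERSIONS)})"
        )

    v = {name: _named_value(wb, name) for name in _SCALAR_FIELDS}

    declarations = []
    if "Pixel datasets" not in wb.sheetnames:
        raise FormatError("workbook lacks the 'Pixel datasets' sheet")
    ws = wb["Pixel datasets"]
    for row in ws.iter_rows(min_row=2, max_col=len(_DECL_HEADER), values_only=True):
        cells = ["" if c is None else str(c).strip() for c in row]
        cells += [""] * (len(_DECL_HEADER) - len(cells))
        if not any(cells):
            continue
        tags = tuple(t.strip() for t in cells[6].split(",") if t.strip())
        declarations.append(
            PixelSetDeclaration(
                filename=cells[0], md5=cells[1], omics_unit_type_name=cells[2],
                strain_name=cells[3], species_name=cells[4],
                description=cells[5], tags=tags,
            )
        )

    missing = [
        field_name
        for field_name, key in (
            ("experiment.description", "experiment_description"),
            ("experiment.omics_area", "experiment_omics_area"),
            ("analysis.description", "analysis_description"),
            ("analysis.secondary_data.filename", "secondary_data_filename"),
            ("analysis.secondary_data.md5", "secondary_data_md5"),
            ("analysis.notebook.filename", "notebook_filename"),
            ("analysis.notebook.md5", "notebook_md5"),
            ("pixeler.name", "pixeler_name"),
        )
        if not v[key]
    ]
    if not declarations:
        missing.append("pixel_datasets (at least one declaration)")
    for i, d in enumerate(declarations, start=1):
        for attr in ("filename", "md5", "omics_unit_type_name", "strain_name",
                     "species_name"):
            if not getattr(d, attr):
                missing.append(f"pixel_datasets[{i}].{attr}")
    if missing:
        raise ValidationError(
            "mandatory workbook fields missing or empty: " + ", ".join(missing)
        )

    try:
        secondary = FileRef(v["secondary_data_filename"], v["secondary_data_md5"])
        notebook = FileRef(v["notebook_filename"], v["notebook_md5"])
        for d in declarations:
            FileRef(d.filename, d.md5)  # md5 syntax check
    except ValidationError as exc:
        raise ValidationError(f"workbook checksum field invalid: {exc}") from exc

    return SubmissionMeta(
        experiment=ExperimentMeta(
            description=v["experiment_description"],
            omics_area_name=v["experiment_omics_area"],
            completed_at=v["experiment_completed_at"],
            released_at=v["experiment_released_at"],
        ),
        analysis=AnalysisMeta(
            description=v["analysis_description"],
            secondary_data=secondary,
            notebook=notebook,
            completed_at=v["analysis_completed_at"],
        ),
        pixeler=PixelerMeta(name=v["pixeler_name"], contact=v["pixeler_contact"]),
        declarations=tuple(declarations),
        template_version=version,
    )


# --------------------------------------------------------------------- #
# Pixel Set TSV files

def parse_pixelset_file(data: bytes | str, permissive: bool = False) -> list[PixelRecord]:
    """Parse a Pixel Set TSV into records, preserving row order.

    Dialect: UTF-8, tab separator, mandatory three-column header, dot
    decimals (scientific notation accepted), one row per Omics Unit.
    Duplicated identifiers, non-numeric or non-finite numbers and empty
    fields are errors; with ``permissive=True`` bad rows are skipped with
    a warning instead (duplicates always fail).
    """
    if isinstance(data, bytes):
        try:
            text = data.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise ParseError(f"pixel set file is not UTF-8: {exc}") from exc
    else:
        text = data
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ParseError("empty file: missing header", line=1)
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if tuple(h.casefold() for h in header) != tuple(h.casefold() for h in PIXELSET_HEADER):
        raise ParseError(
            f"bad header {header!r}; expected {PIXELSET_HEADER!r}", line=1
        )

    records: list[PixelRecord] = []
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            if len(fields) != 3:
                raise ParseError(f"expected 3 tab-separated fields, got {len(fields)}",
                                 line=lineno)
            ident, value_s, qs_s = (f.strip() for f in fields)
            if not ident:
                raise ParseError("empty Omics Unit identifier", line=lineno)
            if not value_s or not qs_s:
                raise ParseError(f"empty numeric field for {ident!r}", line=lineno)
            try:
                value, qs = float(value_s), float(qs_s)
            except ValueError:
                raise ParseError(
                    f"non-numeric value/quality score for {ident!r}:"
                    f" {value_s!r} / {qs_s!r}",
                    line=lineno,
                ) from None
            if not (math.isfinite(value) and math.isfinite(qs)):
                raise ParseError(f"non-finite number for {ident!r}", line=lineno)
        except ParseError as exc:
            if permissive:
                warnings.warn(f"skipping bad row: {exc}", stacklevel=2)
                continue
            raise
        if ident in seen:
            duplicates.append(ident)
        seen[ident] = lineno
        records.append(PixelRecord(ident, value, qs))
    if duplicates:
        raise ParseError(
            "duplicated Omics Unit identifiers: " + ", ".join(sorted(set(duplicates)))
        )
    return records


def write_pixelset_file(records: list[PixelRecord]) -> bytes:
    lines = ["\t".join(PIXELSET_HEADER)]
    for r in records:
        lines.append(
            f"{r.omics_unit_identifier}\t{format_number(r.value)}"
            f"\t{format_number(r.quality_score)}"
        )
    return ("\n".join(lines) + "\n").encode("utf-8")


# --------------------------------------------------------------------- #
# archives

def md5_hex(data: bytes) -> str:
    return hashlib.md5(data).hexdigest()


def read_archive(zip_bytes: bytes) -> ArchiveBundle:
    """Open a submission ZIP, parse its workbook and verify checksums."""
    members = _zip_members(zip_bytes)
    if WORKBOOK_MEMBER in members:
        wb_name = WORKBOOK_MEMBER
    else:
        xlsx = [n for n in members if n.lower().endswith(".xlsx")]
        if len(xlsx) != 1:
            raise ArchiveError(
                f"archive must contain exactly one metadata workbook"
                f" ({WORKBOOK_MEMBER}); found {sorted(xlsx) or 'none'}"
            )
        wb_name = xlsx[0]
    meta = parse_workbook(members[wb_name])

    report = []
    for ref in meta.declared_files():
        if ref.filename not in members:
            raise ArchiveError(
                f"member {ref.filename!r} is declared in the workbook"
                " but absent from the archive"
            )
        report.append(
            ChecksumEntry(ref.filename, ref.md5, md5_hex(members[ref.filename]))
        )
    return ArchiveBundle(meta=meta, files=members, checksum_report=tuple(report))


def write_archive(
    meta: SubmissionMeta,
    data_files: dict[str, bytes],
    choices: dict[str, list[str]] | None = None,
) -> bytes:
    """Bundle metadata + data files into a deterministic submission ZIP.

    Checksums in ``meta`` are recomputed from ``data_files`` so the
    written archive is always self-consistent.
    """
    refs = {
        name: FileRef(name, md5_hex(content), len(content))
        for name, content in data_files.items()
    }

    def _fix(ref: FileRef | None) -> FileRef | None:
        if ref is None:
            return None
        if ref.filename not in refs:
            raise ArchiveError(f"declared file {ref.filename!r} not supplied")
        return refs[ref.filename]

    analysis = replace(
        meta.analysis,
        secondary_data=_fix(meta.analysis.secondary_data),
        notebook=_fix(meta.analysis.notebook),
    )
    declarations = []
    for d in meta.declarations:
        if d.filename not in refs:
            raise ArchiveError(f"declared pixel set file {d.filename!r} not supplied")
        declarations.append(replace(d, md5=refs[d.filename].md5))
    meta = replace(meta, analysis=analysis, declarations=tuple(declarations))

    members = dict(data_files)
    members[WORKBOOK_MEMBER] = build_workbook(meta, choices=choices)
    return deterministic_zip(members)
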