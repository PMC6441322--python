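"""Import workflow: the six-step submission state machine.

A submission advances through *upload* → *meta checks* → *annotation
confirmation* → *tags* (optional) → *final import*. The template-download
step precedes the session (the template leaves the system; see
:func:`pixelbase.archive.generate_template`). Up to the final step the
store is never touched: checksum verification, template-version gating
and Omics Unit resolution (step "Meta") read the store but write nothing,
and the final import persists everything in one atomic transaction — a
failed session leaves the store byte-identical to its prior state.

A failed session is terminal; users start a new session rather than
repairing one in place.
"""

from __future__ import annotations

import enum
import uuid
from dataclasses import dataclass, field

from . import archive as archive_io
from .errors import ArchiveError, PixelbaseError, StateError, ValidationError
from .models import (
    Analysis,
    Experiment,
    FileRef,
    Pixel,
    Pixeler,
    TagPath,
)
from .store import PixelStore


class SessionState(enum.Enum):
    CREATED = "created"
    UPLOADED = "uploaded"
    META_CHECKED = "meta_checked"
    ANNOTATED = "annotated"
    TAGGED = "tagged"
    IMPORTED = "imported"
    FAILED = "failed"


@dataclass(frozen=True)
class MetaReport:
    """Outcome of the automatic integrity checks (no store mutation)."""

    version_ok: bool
    checksum_report: tuple[archive_io.ChecksumEntry, ...]
    missing_units: dict[str, list[str]]  # pixel set filename -> missing ids

    @property
    def ok(self) -> bool:
        return (
            self.version_ok
            and all(e.match for e in self.checksum_report)
            and not any(self.missing_units.values())
        )


@dataclass(frozen=True)
class ImportResult:
    pixel_sets_created: int
    pixels_created: int
    pixel_set_uids: tuple[str, ...] = ()


@dataclass
class ImportSession:
    """One submission attempt; see the module docstring for the lifecycle."""

    id: str = field(default_factory=lambda: uuid.uuid4().hex)
    state: SessionState = SessionState.CREATED
    bundle: archive_io.ArchiveBundle | None = None
    pending_tags: set[TagPath] = field(default_factory=set)
    report: list[str] = field(default_factory=list)

    # populated by the successive steps
    _records: dict[str, list[archive_io.PixelRecord]] = field(default_factory=dict)
    _staged: dict | None = None

    # -------------------------------------------------------------- #

    def _require(self, *states: SessionState) -> None:
        if self.state not in states:
            allowed = "/".join(s.value for s in states)
            raise StateError(
                f"operation requires session state {allowed}, not {self.state.value}"
            )

    def _fail(self, exc: PixelbaseError) -> PixelbaseError:
        self.state = SessionState.FAILED
        self.report.append(f"failed: {exc}")
        return exc

    # -------------------------------------------------------------- #
    # step 2: Upload

    def attach_archive(self, zip_bytes: bytes) -> "ImportSession":
        """Read the submission ZIP into the session; the store is untouched."""
        self._require(SessionState.CREATED)
        try:
            self.bundle = archive_io.read_archive(zip_bytes)
        except PixelbaseError as exc:
            raise self._fail(exc)
        self.state = SessionState.UPLOADED
        self.report.append(
            f"uploaded archive with {len(self.bundle.meta.declarations)}"
            " pixel set declaration(s)"
        )
        return self

    # -------------------------------------------------------------- #
    # step 3: Meta — automatic checks, nothing imported

    def run_meta_checks(self, store: PixelStore) -> MetaReport:
        self._require(SessionState.UPLOADED)
        bundle = self.bundle
        assert bundle is not None

        version_ok = True  # read_archive already gated the version
        mismatches = bundle.checksum_mismatches()
        for entry in bundle.checksum_report:
            self.report.append(
                f"checksum {entry.filename}: "
                + ("ok" if entry.match
                   else f"MISMATCH ({entry.declared} != {entry.computed})")
            )
        if mismatches:
            names = ", ".join(e.filename for e in mismatches)
            raise self._fail(ValidationError(f"md5 checksum mismatch for: {names}"))

        missing_units: dict[str, list[str]] = {}
        records: dict[str, list[archive_io.PixelRecord]] = {}
        try:
            for decl in bundle.meta.declarations:
                recs = archive_io.parse_pixelset_file(bundle.files[decl.filename])
                records[decl.filename] = recs
                _, missing = store.lookup_omics_units(
                    [r.omics_unit_identifier for r in recs],
                    strain=decl.strain_name,
                    unit_type=decl.omics_unit_type_name,
                )
                missing_units[decl.filename] = missing
        except PixelbaseError as exc:
            raise self._fail(exc)

        mreport = MetaReport(
            version_ok=version_ok,
            checksum_report=bundle.checksum_report,
            missing_units=missing_units,
        )
        missing_all = sorted({m for ms in missing_units.values() for m in ms})
        if missing_all:
            raise self._fail(
                ValidationError(
                    "unregistered Omics Units (pre-register them first): "
                    + ", ".join(missing_all)
                )
            )
        self._records = records
        self.state = SessionState.META_CHECKED
        self.report.append("meta checks passed")
        return mreport

    # -------------------------------------------------------------- #
    # step 4: Annotation — user-confirmed resolution of declared names

    def confirm_annotation(self, store: PixelStore) -> "ImportSession":
        self._require(SessionState.META_CHECKED)
        meta = self.bundle.meta
        staged: dict = {"declarations": []}
        try:
            try:
                staged["omics_area"] = store.get_omics_area(meta.experiment.omics_area_name)
            except PixelbaseError:
                raise ValidationError(
                    f"omics_area: {meta.experiment.omics_area_name!r} is not registered"
                )
            for decl in meta.declarations:
                entry = {"decl": decl}
                try:
                    entry["species"] = store.get_species(decl.species_name)
                except PixelbaseError:
                    raise ValidationError(
                        f"species: {decl.species_name!r} is not registered"
                    )
                try:
                    entry["strain"] = store.get_strain(decl.strain_name, decl.species_name)
                except PixelbaseError:
                    raise ValidationError(
                        f"strain: {decl.strain_name!r} is not registered"
                        f" for species {decl.species_name!r}"
                    )
                try:
                    entry["unit_type"] = store.get_unit_type(decl.omics_unit_type_name)
                except PixelbaseError:
                    raise ValidationError(
                        f"omics_unit_type: {decl.omics_unit_type_name!r} is not registered"
                    )
                staged["declarations"].append(entry)
        except PixelbaseError as exc:
            raise self._fail(exc)

        staged["experiment"] = Experiment(
            description=meta.experiment.description,
            omics_area=staged["omics_area"],
            completed_at=meta.experiment.completed_at,
            released_at=meta.experiment.released_at or None,
        )
        staged["pixeler"] = Pixeler(meta.pixeler.name, meta.pixeler.contact)
        self._staged = staged
        self.state = SessionState.ANNOTATED
        self.report.append("annotation confirmed")
        return self

    def annotation_summary(self) -> str:
        """Human-readable summary of what finalize would persist."""
        self._require(SessionState.ANNOTATED, SessionState.TAGGED)
        meta = self.bundle.meta
        lines = [
            f"experiment: {meta.experiment.description}",
            f"omics area: {meta.experiment.omics_area_name}",
            f"analysis: {meta.analysis.description}",
            f"pixeler: {meta.pixeler.name}",
        ]
        for decl in meta.declarations:
            lines.append(
                f"pixel set {decl.filename}: {decl.species_name} / {decl.strain_name}"
                f" / {decl.omics_unit_type_name},"
                f" {len(self._records[decl.filename])} pixels"
            )
        return "\n".join(lines)

    # -------------------------------------------------------------- #
    # step 5: Tags (optional)

    def assign_tags(self, tags: set[TagPath | str]) -> "ImportSession":
        self._require(SessionState.ANNOTATED)
        self.pending_tags = {TagPath.parse(t) for t in tags}
        self.state = SessionState.TAGGED
        self.report.append(f"assigned {len(self.pending_tags)} tag(s)")
        return self

    # -------------------------------------------------------------- #
    # step 6: Import archive

    def finalize(self, store: PixelStore, _failpoint=None) -> ImportResult:
        """Persist everything in one transaction; all-or-nothing.

        ``_failpoint`` is a fault-injection hook (called mid-transaction)
        used to exercise the rollback guarantee.
        """
        self._require(SessionState.ANNOTATED, SessionState.TAGGED)
        meta = self.bundle.meta
        staged = self._staged
        created_sets: list[str] = []
        pixels_created = 0
        try:
            with store.transaction():
                pixeler = store.add_pixeler(staged["pixeler"])
                experiment = store.add_experiment(staged["experiment"])
                analysis = store.add_analysis(
                    Analysis(
                        description=meta.analysis.description,
                        experiment=experiment,
                        secondary_data_ref=meta.analysis.secondary_data,
                        notebook_ref=meta.analysis.notebook,
                        pixeler=pixeler,
                        completed_at=meta.analysis.completed_at,
                    )
                )
                for entry in staged["declarations"]:
                    decl = entry["decl"]
                    # workbook-declared tags and step-5 tags are unioned
                    tags = {TagPath.parse(t) for t in decl.tags} | self.pending_tags
                    pixel_set = store.add_pixel_set(
                        source_filename=decl.filename, analysis=analysis, tags=tags
                    )
                    if _failpoint is not None:
                        _failpoint()
                    recs = self._records[decl.filename]
                    units, missing = store.lookup_omics_units(
                        [r.omics_unit_identifier for r in recs],
                        strain=entry["strain"],
                        unit_type=entry["unit_type"],
                    )
                    if missing:  # guarded at meta_checks; defensive re-check
                        raise ValidationError(
                            "unregistered Omics Units: " + ", ".join(missing)
                        )
                    pixels = [
                        Pixel(unit, rec.value, rec.quality_score)
                        for unit, rec in zip(units, recs)
                    ]
                    store.add_pixels(pixel_set, pixels)
                    created_sets.append(pixel_set.uid)
                    pixels_created += len(pixels)
        except BaseException as exc:
            self.state = SessionState.FAILED
            self.report.append(f"failed: import rolled back ({exc})")
            raise
        self.state = SessionState.IMPORTED
        self.report.append(
            f"imported {len(created_sets)} pixel set(s), {pixels_created} pixel(s)"
        )
        store.log_session(
            self.id, self.state.value, meta.pixeler.name, self.report[-1]
        )
        return ImportResult(
            pixel_sets_created=len(created_sets),
            pixels_created=pixels_created,
            pixel_set_uids=tuple(created_sets),
        )


def new_session() -> ImportSession:
    return ImportSession()


def run_import(
    store: PixelStore,
    zip_bytes: bytes,
    tags: set[TagPath | str] = frozenset(),
) -> ImportResult:
    """Drive a full session (upload → checks → confirm → tags → import)."""
    session = new_session()
    session.attach_archive(zip_bytes)
    session.run_meta_checks(store)
    session.confirm_annotation(store)
    if tags:
        session.assign_tags(set(tags))
    return session.finalize(store)
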