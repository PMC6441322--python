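"""Persistent store for Pixel Sets and their annotation context.

A single-file embedded SQLite database (``:memory:`` by default) with
referential integrity enforced both by SQL foreign keys and by explicit
checks at registration time. Context entities — Species, Strain,
OmicsUnitType, OmicsArea, OmicsUnit — must be registered *before* any
Pixel Set import; submission-time entities are only ever written inside
the import workflow's transaction.

The store is append-only apart from tag edits: records are never deleted,
matching the provenance-keeping role of the catalog.
"""

from __future__ import annotations

import hashlib
import sqlite3
import uuid
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

from .errors import NotFoundError, UniquenessError, ValidationError
from .models import (
    Analysis,
    Experiment,
    FileRef,
    OmicsArea,
    OmicsUnit,
    OmicsUnitType,
    Pixel,
    Pixeler,
    PixelSet,
    Species,
    Strain,
    TagPath,
)

_SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS species (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT '',
    reference_url TEXT
);
CREATE UNIQUE INDEX IF NOT EXISTS ix_species_name ON species (lower(name));

CREATE TABLE IF NOT EXISTS strain (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    species_id INTEGER NOT NULL REFERENCES species(id)
);
CREATE UNIQUE INDEX IF NOT EXISTS ix_strain_name
    ON strain (lower(name), species_id);

CREATE TABLE IF NOT EXISTS omics_unit_type (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT ''
);
CREATE UNIQUE INDEX IF NOT EXISTS ix_unit_type_name
    ON omics_unit_type (lower(name));

CREATE TABLE IF NOT EXISTS omics_area (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT ''
);
CREATE UNIQUE INDEX IF NOT EXISTS ix_area_name ON omics_area (lower(name));

CREATE TABLE IF NOT EXISTS omics_unit (
    id INTEGER PRIMARY KEY,
    identifier TEXT NOT NULL,
    description TEXT NOT NULL,
    reference_url TEXT NOT NULL,
    strain_id INTEGER NOT NULL REFERENCES strain(id),
    unit_type_id INTEGER NOT NULL REFERENCES omics_unit_type(id),
    UNIQUE (identifier, strain_id, unit_type_id)
);

CREATE TABLE IF NOT EXISTS experiment (
    id INTEGER PRIMARY KEY,
    description TEXT NOT NULL,
    omics_area_id INTEGER NOT NULL REFERENCES omics_area(id),
    completed_at TEXT NOT NULL DEFAULT '',
    released_at TEXT
);

CREATE TABLE IF NOT EXISTS pixeler (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    contact TEXT NOT NULL DEFAULT ''
);

CREATE TABLE IF NOT EXISTS analysis (
    id INTEGER PRIMARY KEY,
    description TEXT NOT NULL,
    experiment_id INTEGER NOT NULL REFERENCES experiment(id),
    secondary_data_filename TEXT NOT NULL,
    secondary_data_md5 TEXT NOT NULL,
    secondary_data_size INTEGER NOT NULL DEFAULT 0,
    notebook_filename TEXT NOT NULL,
    notebook_md5 TEXT NOT NULL,
    notebook_size INTEGER NOT NULL DEFAULT 0,
    pixeler_id INTEGER NOT NULL REFERENCES pixeler(id),
    completed_at TEXT NOT NULL DEFAULT ''
);

CREATE TABLE IF NOT EXISTS pixel_set (
    id INTEGER PRIMARY KEY,
    uid TEXT NOT NULL UNIQUE,
    source_filename TEXT NOT NULL,
    analysis_id INTEGER NOT NULL REFERENCES analysis(id),
    pixel_count INTEGER NOT NULL DEFAULT 0
);

CREATE TABLE IF NOT EXISTS pixel (
    id INTEGER PRIMARY KEY,
    pixel_set_id INTEGER NOT NULL REFERENCES pixel_set(id),
    omics_unit_id INTEGER NOT NULL REFERENCES omics_unit(id),
    value REAL NOT NULL,
    quality_score REAL NOT NULL,
    UNIQUE (pixel_set_id, omics_unit_id)
);

CREATE TABLE IF NOT EXISTS pixel_set_tag (
    pixel_set_id INTEGER NOT NULL REFERENCES pixel_set(id),
    tag TEXT NOT NULL
);
CREATE UNIQUE INDEX IF NOT EXISTS ix_pixel_set_tag
    ON pixel_set_tag (pixel_set_id, lower(tag));

CREATE TABLE IF NOT EXISTS import_session_log (
    id INTEGER PRIMARY KEY,
    session_uid TEXT NOT NULL,
    state TEXT NOT NULL,
    pixeler_name TEXT NOT NULL DEFAULT '',
    detail TEXT NOT NULL DEFAULT '',
    logged_at TEXT NOT NULL DEFAULT (datetime('now'))
);
"""

#: Tables whose row counts describe the store's content.
_TABLES = (
    "species",
    "strain",
    "omics_unit_type",
    "omics_area",
    "omics_unit",
    "experiment",
    "pixeler",
    "analysis",
    "pixel_set",
    "pixel",
    "pixel_set_tag",
)


@dataclass
class IntegrityIssue:
    kind: str  # "dangling" | "count_mismatch"
    detail: str


class PixelStore:
    """Open (creating/migrating if needed) a pixel store at ``path``."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._db = sqlite3.connect(path)
        # autocommit outside explicit transaction() blocks, so single
        # registrations persist immediately and finalize controls atomicity
        self._db.isolation_level = None
        self._db.row_factory = sqlite3.Row
        self._db.execute("PRAGMA foreign_keys = ON")
        self._migrate()

    def _migrate(self) -> None:
        version = self._db.execute("PRAGMA user_version").fetchone()[0]
        if version > _SCHEMA_VERSION:
            raise ValidationError(
                f"store schema version {version} is newer than supported ({_SCHEMA_VERSION})"
            )
        with self._db:
            self._db.executescript(_SCHEMA)
            self._db.execute(f"PRAGMA user_version = {_SCHEMA_VERSION}")

    def close(self) -> None:
        self._db.close()

    def __enter__(self) -> "PixelStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # ------------------------------------------------------------------ #
    # transactions

    @contextmanager
    def transaction(self):
        """All writes inside the block commit atomically or not at all."""
        if self._db.in_transaction:
            raise ValidationError("nested transactions are not supported")
        self._db.execute("BEGIN IMMEDIATE")
        try:
            yield
        except BaseException:
            self._db.rollback()
            raise
        else:
            self._db.commit()

    def _write(self, sql: str, params: tuple) -> int:
        try:
            cur = self._db.execute(sql, params)
        except sqlite3.IntegrityError as exc:
            raise UniquenessError(str(exc)) from exc
        return cur.lastrowid

    # ------------------------------------------------------------------ #
    # pre-registration of context entities

    def register_species(
        self, name: str, description: str = "", reference_url: str | None = None
    ) -> Species:
        sp = Species(name=name, description=description, reference_url=reference_url)
        rid = self._write(
            "INSERT INTO species (name, description, reference_url) VALUES (?, ?, ?)",
            (sp.name, sp.description, sp.reference_url),
        )
        return Species(sp.name, sp.description, sp.reference_url, id=rid)

    def register_strain(self, name: str, species: Species | str) -> Strain:
        sp = self.get_species(species) if isinstance(species, str) else species
        if sp.id is None:
            sp = self.get_species(sp.name)
        st = Strain(name=name, species=sp)
        rid = self._write(
            "INSERT INTO strain (name, species_id) VALUES (?, ?)", (st.name, sp.id)
        )
        return Strain(st.name, sp, id=rid)

    def register_omics_unit_type(self, name: str, description: str = "") -> OmicsUnitType:
        t = OmicsUnitType(name=name, description=description)
        rid = self._write(
            "INSERT INTO omics_unit_type (name, description) VALUES (?, ?)",
            (t.name, t.description),
        )
        return OmicsUnitType(t.name, t.description, id=rid)

    def register_omics_area(self, name: str, description: str = "") -> OmicsArea:
        a = OmicsArea(name=name, description=description)
        rid = self._write(
            "INSERT INTO omics_area (name, description) VALUES (?, ?)",
            (a.name, a.description),
        )
        return OmicsArea(a.name, a.description, id=rid)

    def register_omics_unit(
        self,
        identifier: str,
        description: str,
        reference_url: str,
        strain: Strain | str,
        unit_type: OmicsUnitType | str,
    ) -> OmicsUnit:
        st = self.get_strain(strain) if isinstance(strain, str) else strain
        ut = self.get_unit_type(unit_type) if isinstance(unit_type, str) else unit_type
        unit = OmicsUnit(
            identifier=identifier,
            description=description,
            reference_url=reference_url,
            strain=st,
            unit_type=ut,
        )
        rid = self._write(
            "INSERT INTO omics_unit (identifier, description, reference_url,"
            " strain_id, unit_type_id) VALUES (?, ?, ?, ?, ?)",
            (unit.identifier, unit.description, unit.reference_url, st.id, ut.id),
        )
        return OmicsUnit(unit.identifier, unit.description, unit.reference_url, st, ut, id=rid)

    # ------------------------------------------------------------------ #
    # lookups

    def _one(self, sql: str, params: tuple, what: str):
        row = self._db.execute(sql, params).fetchone()
        if row is None:
            raise NotFoundError(f"{what} not found")
        return row

    def get_species(self, name: str) -> Species:
        row = self._one(
            "SELECT * FROM species WHERE lower(name) = lower(?)", (name,), f"species {name!r}"
        )
        return Species(row["name"], row["description"], row["reference_url"], id=row["id"])

    def get_strain(self, name: str, species: str | None = None) -> Strain:
        sql = (
            "SELECT strain.*, species.name AS sp_name FROM strain"
            " JOIN species ON species.id = strain.species_id"
            " WHERE lower(strain.name) = lower(?)"
        )
        params: tuple = (name,)
        if species is not None:
            sql += " AND lower(species.name) = lower(?)"
            params += (species,)
        row = self._one(sql, params, f"strain {name!r}")
        return Strain(row["name"], self.get_species(row["sp_name"]), id=row["id"])

    def get_unit_type(self, name: str) -> OmicsUnitType:
        row = self._one(
            "SELECT * FROM omics_unit_type WHERE lower(name) = lower(?)",
            (name,),
            f"omics unit type {name!r}",
        )
        return OmicsUnitType(row["name"], row["description"], id=row["id"])

    def get_omics_area(self, name: str) -> OmicsArea:
        row = self._one(
            "SELECT * FROM omics_area WHERE lower(name) = lower(?)",
            (name,),
            f"omics area {name!r}",
        )
        return OmicsArea(row["name"], row["description"], id=row["id"])

    def species_names(self) -> list[str]:
        return [r[0] for r in self._db.execute("SELECT name FROM species ORDER BY name")]

    def strain_names(self) -> list[str]:
        return [r[0] for r in self._db.execute("SELECT name FROM strain ORDER BY name")]

    def unit_type_names(self) -> list[str]:
        return [r[0] for r in self._db.execute("SELECT name FROM omics_unit_type ORDER BY name")]

    def omics_area_names(self) -> list[str]:
        return [r[0] for r in self._db.execute("SELECT name FROM omics_area ORDER BY name")]

    def _unit_from_row(self, row) -> OmicsUnit:
        return OmicsUnit(
            row["identifier"],
            row["description"],
            row["reference_url"],
            self.get_strain(row["st_name"]),
            self.get_unit_type(row["ut_name"]),
            id=row["id"],
        )

    def get_omics_unit(
        self, identifier: str, strain: Strain | str, unit_type: OmicsUnitType | str
    ) -> OmicsUnit:
        st = self.get_strain(strain) if isinstance(strain, str) else strain
        ut = self.get_unit_type(unit_type) if isinstance(unit_type, str) else unit_type
        row = self._one(
            "SELECT omics_unit.*, strain.name AS st_name, omics_unit_type.name AS ut_name"
            " FROM omics_unit"
            " JOIN strain ON strain.id = omics_unit.strain_id"
            " JOIN omics_unit_type ON omics_unit_type.id = omics_unit.unit_type_id"
            " WHERE identifier = ? AND strain_id = ? AND unit_type_id = ?",
            (identifier, st.id, ut.id),
            f"omics unit {identifier!r}",
        )
        return self._unit_from_row(row)

    def lookup_omics_units(
        self,
        identifiers: list[str],
        strain: Strain | str,
        unit_type: OmicsUnitType | str,
    ) -> tuple[list[OmicsUnit], list[str]]:
        """Partition ``identifiers`` into (registered units, missing ids).

        Order is preserved in both outputs; the two together cover the
        input exactly. A missing identifier is data, not an error — the
        import workflow turns a non-empty missing list into a failure.
        """
        found: list[OmicsUnit] = []
        missing: list[str] = []
        for ident in identifiers:
            try:
                found.append(self.get_omics_unit(ident, strain, unit_type))
            except NotFoundError:
                missing.append(ident)
        return found, missing

    # ------------------------------------------------------------------ #
    # submission-time writes (called inside the import workflow's
    # transaction; usable directly for programmatic population)

    def add_pixeler(self, pixeler: Pixeler) -> Pixeler:
        rid = self._write(
            "INSERT INTO pixeler (name, contact) VALUES (?, ?)",
            (pixeler.name, pixeler.contact),
        )
        return Pixeler(pixeler.name, pixeler.contact, id=rid)

    def add_experiment(self, exp: Experiment) -> Experiment:
        area = exp.omics_area
        if area.id is None:
            area = self.get_omics_area(area.name)
        rid = self._write(
            "INSERT INTO experiment (description, omics_area_id, completed_at, released_at)"
            " VALUES (?, ?, ?, ?)",
            (exp.description, area.id, exp.completed_at, exp.released_at),
        )
        return Experiment(exp.description, area, exp.completed_at, exp.released_at, id=rid)

    def add_analysis(self, an: Analysis) -> Analysis:
        if an.experiment.id is None or an.pixeler.id is None:
            raise ValidationError("analysis requires persisted experiment and pixeler")
        rid = self._write(
            "INSERT INTO analysis (description, experiment_id,"
            " secondary_data_filename, secondary_data_md5, secondary_data_size,"
            " notebook_filename, notebook_md5, notebook_size, pixeler_id, completed_at)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            (
                an.description,
                an.experiment.id,
                an.secondary_data_ref.filename,
                an.secondary_data_ref.md5,
                an.secondary_data_ref.byte_size,
                an.notebook_ref.filename,
                an.notebook_ref.md5,
                an.notebook_ref.byte_size,
                an.pixeler.id,
                an.completed_at,
            ),
        )
        return Analysis(
            an.description,
            an.experiment,
            an.secondary_data_ref,
            an.notebook_ref,
            an.pixeler,
            an.completed_at,
            id=rid,
        )

    def add_pixel_set(
        self,
        source_filename: str,
        analysis: Analysis,
        tags: set[TagPath] = frozenset(),
        uid: str | None = None,
    ) -> PixelSet:
        if analysis.id is None:
            raise ValidationError("pixel set requires a persisted analysis")
        uid = uid or uuid.uuid4().hex
        rid = self._write(
            "INSERT INTO pixel_set (uid, source_filename, analysis_id, pixel_count)"
            " VALUES (?, ?, ?, 0)",
            (uid, source_filename, analysis.id),
        )
        tag_paths = frozenset(TagPath.parse(t) for t in tags)
        for tag in sorted(tag_paths, key=str):
            self._write(
                "INSERT INTO pixel_set_tag (pixel_set_id, tag) VALUES (?, ?)",
                (rid, str(tag)),
            )
        return PixelSet(uid, source_filename, analysis, tag_paths, 0, id=rid)

    def add_pixels(self, pixel_set: PixelSet, pixels: list[Pixel]) -> PixelSet:
        """Append pixels to a set, keeping its pixel_count consistent.

        Quality scores are typically p-values; a score outside [0, 1] is
        allowed (the field only promises "a quality score") but warned
        about.
        """
        for px in pixels:
            if px.omics_unit.id is None:
                raise ValidationError("pixel references an unregistered omics unit")
            if not (0.0 <= px.quality_score <= 1.0):
                warnings.warn(
                    f"quality score {px.quality_score} for {px.omics_unit.identifier}"
                    " lies outside [0, 1]",
                    stacklevel=2,
                )
            self._write(
                "INSERT INTO pixel (pixel_set_id, omics_unit_id, value, quality_score)"
                " VALUES (?, ?, ?, ?)",
                (pixel_set.id, px.omics_unit.id, px.value, px.quality_score),
            )
        self._write(
            "UPDATE pixel_set SET pixel_count = pixel_count + ? WHERE id = ?",
            (len(pixels), pixel_set.id),
        )
        count = self._db.execute(
            "SELECT pixel_count FROM pixel_set WHERE id = ?", (pixel_set.id,)
        ).fetchone()[0]
        return PixelSet(
            pixel_set.uid,
            pixel_set.source_filename,
            pixel_set.analysis,
            pixel_set.tags,
            count,
            id=pixel_set.id,
        )

    def set_tags(self, pixel_set: PixelSet, tags: set[TagPath | str]) -> None:
        """Replace the tags of a pixel set (tags may be edited at any time)."""
        paths = {TagPath.parse(t) for t in tags}
        with self.transaction():
            self._db.execute(
                "DELETE FROM pixel_set_tag WHERE pixel_set_id = ?", (pixel_set.id,)
            )
            for tag in sorted(paths, key=str):
                self._db.execute(
                    "INSERT INTO pixel_set_tag (pixel_set_id, tag) VALUES (?, ?)",
                    (pixel_set.id, str(tag)),
                )

    def log_session(self, session_uid: str, state: str, pixeler_name: str, detail: str) -> None:
        self._write(
            "INSERT INTO import_session_log (session_uid, state, pixeler_name, detail)"
            " VALUES (?, ?, ?, ?)",
            (session_uid, state, pixeler_name, detail),
        )

    # ------------------------------------------------------------------ #
    # reads used by the query/export layers

    def pixel_sets(self) -> list[PixelSet]:
        rows = self._db.execute("SELECT uid FROM pixel_set ORDER BY id").fetchall()
        return [self.get_pixel_set(r["uid"]) for r in rows]

    def get_pixel_set(self, uid: str) -> PixelSet:
        row = self._one(
            "SELECT * FROM pixel_set WHERE uid = ?", (uid,), f"pixel set {uid!r}"
        )
        analysis = self._get_analysis(row["analysis_id"])
        tags = frozenset(
            TagPath.parse(r["tag"])
            for r in self._db.execute(
                "SELECT tag FROM pixel_set_tag WHERE pixel_set_id = ?", (row["id"],)
            )
        )
        return PixelSet(
            row["uid"], row["source_filename"], analysis, tags, row["pixel_count"], id=row["id"]
        )

    def _get_analysis(self, analysis_id: int) -> Analysis:
        row = self._one(
            "SELECT * FROM analysis WHERE id = ?", (analysis_id,), f"analysis {analysis_id}"
        )
        exp_row = self._one(
            "SELECT experiment.*, omics_area.name AS area_name FROM experiment"
            " JOIN omics_area ON omics_area.id = experiment.omics_area_id"
            " WHERE experiment.id = ?",
            (row["experiment_id"],),
            "experiment",
        )
        experiment = Experiment(
            exp_row["description"],
            self.get_omics_area(exp_row["area_name"]),
            exp_row["completed_at"],
            exp_row["released_at"],
            id=exp_row["id"],
        )
        px_row = self._one(
            "SELECT * FROM pixeler WHERE id = ?", (row["pixeler_id"],), "pixeler"
        )
        pixeler = Pixeler(px_row["name"], px_row["contact"], id=px_row["id"])
        return Analysis(
            row["description"],
            experiment,
            FileRef(row["secondary_data_filename"], row["secondary_data_md5"],
                    row["secondary_data_size"]),
            FileRef(row["notebook_filename"], row["notebook_md5"], row["notebook_size"]),
            pixeler,
            row["completed_at"],
            id=row["id"],
        )

    def pixels(self, pixel_set: PixelSet) -> list[Pixel]:
        rows = self._db.execute(
            "SELECT pixel.id AS px_id, pixel.value, pixel.quality_score,"
            " omics_unit.*, strain.name AS st_name, omics_unit_type.name AS ut_name"
            " FROM pixel"
            " JOIN omics_unit ON omics_unit.id = pixel.omics_unit_id"
            " JOIN strain ON strain.id = omics_unit.strain_id"
            " JOIN omics_unit_type ON omics_unit_type.id = omics_unit.unit_type_id"
            " WHERE pixel.pixel_set_id = ? ORDER BY pixel.id",
            (pixel_set.id,),
        ).fetchall()
        return [
            Pixel(self._unit_from_row(r), r["value"], r["quality_score"], id=r["px_id"])
            for r in rows
        ]

    # ------------------------------------------------------------------ #
    # integrity and content fingerprinting

    def counts(self) -> dict[str, int]:
        return {
            t: self._db.execute(f"SELECT count(*) FROM {t}").fetchone()[0] for t in _TABLES
        }

    def content_digest(self) -> str:
        """MD5 over every row of every content table (order-canonical).

        Two stores with identical content produce identical digests; used
        to assert that failed imports leave the store untouched.
        """
        h = hashlib.md5()
        for table in _TABLES:
            h.update(table.encode())
            cols = [r[1] for r in self._db.execute(f"PRAGMA table_info({table})")]
            order = ", ".join(cols)
            for row in self._db.execute(f"SELECT * FROM {table} ORDER BY {order}"):
                h.update(repr(tuple(row)).encode())
        return h.hexdigest()

    def integrity_report(self) -> list[IntegrityIssue]:
        """Walk every reference and recount pixels; empty list means healthy."""
        issues: list[IntegrityIssue] = []
        for row in self._db.execute("PRAGMA foreign_key_check"):
            issues.append(
                IntegrityIssue("dangling", f"table {row[0]} row {row[1]} -> {row[2]}")
            )
        refs = [
            ("strain", "species_id", "species"),
            ("omics_unit", "strain_id", "strain"),
            ("omics_unit", "unit_type_id", "omics_unit_type"),
            ("experiment", "omics_area_id", "omics_area"),
            ("analysis", "experiment_id", "experiment"),
            ("analysis", "pixeler_id", "pixeler"),
            ("pixel_set", "analysis_id", "analysis"),
            ("pixel", "pixel_set_id", "pixel_set"),
            ("pixel", "omics_unit_id", "omics_unit"),
            ("pixel_set_tag", "pixel_set_id", "pixel_set"),
        ]
        for table, col, target in refs:
            q = (
                f"SELECT {table}.id FROM {table}"
                f" LEFT JOIN {target} ON {target}.id = {table}.{col}"
                f" WHERE {target}.id IS NULL"
            ) if table != "pixel_set_tag" else (
                f"SELECT rowid FROM {table}"
                f" WHERE {col} NOT IN (SELECT id FROM {target})"
            )
            for (rid,) in self._db.execute(q):
                issues.append(
                    IntegrityIssue("dangling", f"{table}.{col} row {rid} -> missing {target}")
                )
        mismatches = self._db.execute(
            "SELECT pixel_set.uid, pixel_set.pixel_count, count(pixel.id) AS actual"
            " FROM pixel_set LEFT JOIN pixel ON pixel.pixel_set_id = pixel_set.id"
            " GROUP BY pixel_set.id HAVING pixel_count != actual"
        ).fetchall()
        for row in mismatches:
            issues.append(
                IntegrityIssue(
                    "count_mismatch",
                    f"pixel set {row['uid']}: pixel_count={row['pixel_count']}"
                    f" but {row['actual']} pixels stored",
                )
            )
        return issues
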