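"""Domain model.

The central record is the *Pixel Set*: the collection of Pixels produced by
one secondary-data analysis. A *Pixel* is a single quantitative measurement
(for example a log2 fold change) plus a quality score (typically a p-value),
bound to one *Omics Unit* — a registered cellular component such as an mRNA
or a protein. Context entities (Species, Strain, OmicsUnitType, OmicsArea,
OmicsUnit) must be registered before any import; submission-time entities
(Experiment, Analysis, Pixeler, PixelSet, Pixel) are created by the import
workflow.

These classes are plain immutable value objects; persistence and uniqueness
enforcement live in :mod:`pixelbase.store`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .errors import ValidationError

MD5_RE = re.compile(r"^[0-9a-f]{32}$")

#: Separator used in the serialized form of hierarchical tag paths.
TAG_SEPARATOR = "/"


def _require_text(value: str, what: str) -> str:
    if not isinstance(value, str) or not value.strip():
        raise ValidationError(f"{what} must be non-empty text")
    return value


@dataclass(frozen=True)
class TagPath:
    """A hierarchical tag, root→leaf, e.g. ``organism/Candida glabrata``.

    Comparison and hashing are case-insensitive. A tag *matches* a filter
    tag when the filter's segments are a case-insensitive prefix of its
    own, so filtering on a tag includes all of its descendants.
    """

    segments: tuple[str, ...]

    def __post_init__(self):
        if not self.segments:
            raise ValidationError("tag path needs at least one segment")
        for seg in self.segments:
            if not seg.strip():
                raise ValidationError("tag path segments must be non-empty")
            if TAG_SEPARATOR in seg:
                raise ValidationError(
                    f"tag segment {seg!r} contains the path separator {TAG_SEPARATOR!r}"
                )
        object.__setattr__(self, "segments", tuple(self.segments))

    @classmethod
    def parse(cls, text: "str | TagPath") -> "TagPath":
        if isinstance(text, TagPath):
            return text
        _require_text(text, "tag path")
        return cls(tuple(part.strip() for part in text.split(TAG_SEPARATOR)))

    def key(self) -> tuple[str, ...]:
        return tuple(s.casefold() for s in self.segments)

    def is_descendant_or_self(self, ancestor: "TagPath") -> bool:
        anc = ancestor.key()
        return self.key()[: len(anc)] == anc

    def __str__(self) -> str:
        return TAG_SEPARATOR.join(self.segments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TagPath):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())


@dataclass(frozen=True)
class Species:
    """A studied organism, e.g. Candida glabrata."""

    name: str
    description: str = ""
    reference_url: str | None = None
    id: int | None = None

    def __post_init__(self):
        _require_text(self.name, "species name")


@dataclass(frozen=True)
class Strain:
    """A genetic background of a Species, e.g. ATCC2001."""

    name: str
    species: Species
    id: int | None = None

    def __post_init__(self):
        _require_text(self.name, "strain name")


@dataclass(frozen=True)
class OmicsUnitType:
    """The kind of monitored cellular component: mRNA, protein, ..."""

    name: str
    description: str = ""
    id: int | None = None

    def __post_init__(self):
        _require_text(self.name, "omics unit type name")


@dataclass(frozen=True)
class OmicsArea:
    """The experimental technology domain: RNA sequencing, mass spectrometry, ..."""

    name: str
    description: str = ""
    id: int | None = None

    def __post_init__(self):
        _require_text(self.name, "omics area name")


@dataclass(frozen=True)
class OmicsUnit:
    """A registered cellular component, scoped to a strain and a unit type.

    The same identifier (a gene accession, say) may legitimately appear
    under several unit types — measured as an mRNA and as a protein — so
    uniqueness is on the triple (identifier, strain, unit_type).
    A description and a reference-database link are mandatory at
    registration time.
    """

    identifier: str
    description: str
    reference_url: str
    strain: Strain
    unit_type: OmicsUnitType
    id: int | None = None

    def __post_init__(self):
        _require_text(self.identifier, "omics unit identifier")
        _require_text(self.description, "omics unit description")
        _require_text(self.reference_url, "omics unit reference_url")


@dataclass(frozen=True)
class Pixeler:
    """The researcher who performed the analysis (annotation, not a login)."""

    name: str
    contact: str = ""
    id: int | None = None

    def __post_init__(self):
        _require_text(self.name, "pixeler name")


@dataclass(frozen=True)
class FileRef:
    """A declared bundled file: name, md5 checksum and size in bytes."""

    filename: str
    md5: str
    byte_size: int = 0

    def __post_init__(self):
        _require_text(self.filename, "filename")
        if not MD5_RE.fullmatch(self.md5):
            raise ValidationError(
                f"md5 for {self.filename!r} must be 32 lowercase hex chars, got {self.md5!r}"
            )
        if self.byte_size < 0:
            raise ValidationError("byte_size must be non-negative")


@dataclass(frozen=True)
class Experiment:
    """The experimental strategy that produced the primary/secondary data."""

    description: str
    omics_area: OmicsArea
    completed_at: str = ""
    released_at: str | None = None
    id: int | None = None

    def __post_init__(self):
        _require_text(self.description, "experiment description")


@dataclass(frozen=True)
class Analysis:
    """The computational procedure that produced the Pixel Sets.

    Carries references (name + checksum) to the secondary-data file and to
    the analysis notebook; both blobs stay outside the store.
    """

    description: str
    experiment: Experiment
    secondary_data_ref: FileRef
    notebook_ref: FileRef
    pixeler: Pixeler
    completed_at: str = ""
    id: int | None = None

    def __post_init__(self):
        _require_text(self.description, "analysis description")


@dataclass(frozen=True)
class PixelSet:
    """A named collection of Pixels from one analysis."""

    uid: str
    source_filename: str
    analysis: Analysis
    tags: frozenset[TagPath] = frozenset()
    pixel_count: int = 0
    id: int | None = None


@dataclass(frozen=True)
class Pixel:
    """One (value, quality score) measurement bound to one Omics Unit."""

    omics_unit: OmicsUnit
    value: float
    quality_score: float
    id: int | None = None

    def __post_init__(self):
        for label, x in (("value", self.value), ("quality_score", self.quality_score)):
            if not isinstance(x, (int, float)) or not math.isfinite(x):
                raise ValidationError(f"pixel {label} must be a finite real, got {x!r}")
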