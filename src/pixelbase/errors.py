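"""Exception hierarchy.

Every error raised by pixelbase derives from :class:`PixelbaseError`, so
callers (and the CLI) can catch one type. Subclasses distinguish the
failure domains: input validation, store uniqueness, archive structure,
file parsing, template versioning and workflow-state misuse.
"""


class PixelbaseError(Exception):
    """Base class for all pixelbase errors."""


class ValidationError(PixelbaseError, ValueError):
    """A field or argument violates its contract (empty name, bad URL...)."""


class UniquenessError(PixelbaseError):
    """An insert would violate a uniqueness constraint of the store."""


class NotFoundError(PixelbaseError, LookupError):
    """A referenced entity does not exist in the store."""


class ArchiveError(PixelbaseError):
    """A submission ZIP is unreadable, or a declared member is missing."""


class FormatError(PixelbaseError):
    """A workbook or data file is not in the expected format."""


class VersionError(FormatError):
    """The metadata workbook declares an unsupported template version."""


class ParseError(FormatError):
    """A tab-separated data file has malformed content."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class StateError(PixelbaseError):
    """An import-session operation was called out of order."""


class JoinError(PixelbaseError):
    """A cross-omics join was refused (e.g. Pixel Sets from different species)."""
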