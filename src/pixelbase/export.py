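"""Cross-omics join and export.

Combines Pixels from several Pixel Sets into one table keyed by Omics
Unit: one row per unit, one (value, quality score) column pair per set.
Units measured under different unit types — the same gene quantified as
an mRNA and as a protein — are joined on their shared identifier within
one strain, which is what makes a transcriptomics/proteomics comparison a
single table. Joining sets from different species is refused.

``intersection`` (the default) keeps units measured in every set;
``union`` keeps all units, with empty cells where a set lacks the
measurement. Values are exported exactly as stored, no transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .archive import format_number
from .errors import JoinError, ValidationError
from .models import Pixel, PixelSet
from .query import Selection, filter_pixels_by_unit_keyword
from .store import PixelStore

JOIN_MODES = ("intersection", "union")


@dataclass(frozen=True)
class OmicsTable:
    """The joined multi-Pixel-Set grid.

    ``columns`` is ``["Omics unit", "Description", "<set>:value",
    "<set>:qs", ...]``; each row holds the identifier, the unit
    description, then one value/qs pair per set (``None`` for a union
    gap). Rows are ordered by identifier, ascending.
    """

    columns: tuple[str, ...]
    rows: tuple[tuple, ...]
    join_mode: str

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def build_multiomics_table(
    store: PixelStore,
    pixel_selections: list[tuple[PixelSet, list[Pixel]]],
    join_mode: str = "intersection",
) -> OmicsTable:
    """Join per-set Pixel lists into an :class:`OmicsTable`.

    ``pixel_selections`` pairs each Pixel Set with the Pixels to export
    from it (typically the output of a keyword filter, or all its
    Pixels). Join keys are (identifier, strain name).
    """
    if join_mode not in JOIN_MODES:
        raise ValidationError(f"join_mode must be one of {JOIN_MODES}, got {join_mode!r}")
    if not pixel_selections:
        raise ValidationError("at least one Pixel Set is required")

    species = {
        p.omics_unit.strain.species.name.casefold()
        for _, pixels in pixel_selections
        for p in pixels
    }
    if len(species) > 1:
        raise JoinError(
            f"refusing to join Pixel Sets across species: {sorted(species)}"
        )

    per_set: list[dict[tuple[str, str], Pixel]] = []
    descriptions: dict[tuple[str, str], str] = {}
    for ps, pixels in pixel_selections:
        keyed: dict[tuple[str, str], Pixel] = {}
        for p in pixels:
            key = (p.omics_unit.identifier, p.omics_unit.strain.name)
            keyed[key] = p
            descriptions.setdefault(key, p.omics_unit.description)
        per_set.append(keyed)

    key_sets = [set(d) for d in per_set]
    if join_mode == "intersection":
        keys = set.intersection(*key_sets) if key_sets else set()
    else:
        keys = set.union(*key_sets) if key_sets else set()

    columns = ["Omics unit", "Description"]
    for ps, _ in pixel_selections:
        columns += [f"{ps.source_filename}:value", f"{ps.source_filename}:qs"]

    rows = []
    for key in sorted(keys):
        row: list = [key[0], descriptions[key]]
        for keyed in per_set:
            p = keyed.get(key)
            if p is None:
                row += [None, None]
            else:
                row += [p.value, p.quality_score]
        rows.append(tuple(row))
    return OmicsTable(tuple(columns), tuple(rows), join_mode)


def export_selection(
    store: PixelStore,
    selection: Selection,
    join_mode: str = "intersection",
    unit_keyword: str | None = None,
) -> OmicsTable:
    """Convenience: filter (optionally) then join a selection of sets."""
    if unit_keyword:
        filtered = filter_pixels_by_unit_keyword(store, selection, unit_keyword)
        pairs = [(ps, filtered[ps.uid]) for ps in selection]
    else:
        pairs = [(ps, store.pixels(ps)) for ps in selection]
    return build_multiomics_table(store, pairs, join_mode=join_mode)


# --------------------------------------------------------------------- #
# TSV serialization

def write_table(table: OmicsTable) -> bytes:
    """Serialize to TSV: dot decimals, scientific below 1e-3, empty cells
    for union gaps."""
    lines = ["\t".join(table.columns)]
    for row in table.rows:
        cells = [str(row[0]), str(row[1])]
        for x in row[2:]:
            cells.append("" if x is None else format_number(x))
        lines.append("\t".join(cells))
    return ("\n".join(lines) + "\n").encode("utf-8")


def read_table(data: bytes, join_mode: str = "intersection") -> OmicsTable:
    """Parse TSV written by :func:`write_table` (cell-exact round trip)."""
    text = data.decode("utf-8")
    lines = [ln for ln in text.splitlines() if ln != ""]
    if not lines:
        raise ValidationError("empty table file")
    columns = tuple(lines[0].split("\t"))
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        cells += [""] * (len(columns) - len(cells))
        row: list = [cells[0], cells[1]]
        for c in cells[2:]:
            row.append(None if c == "" else float(c))
        rows.append(tuple(row))
    return OmicsTable(columns, tuple(rows), join_mode)
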