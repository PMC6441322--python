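"""Exploration of stored Pixel Sets.

Faceted filtering (species / omics unit type / omics area / tags), free
keyword search over the Analysis and Experiment descriptions, a selection
basket, per-set value and quality-score summaries, and keyword filtering
of Pixels by their Omics Unit description.

Facet semantics: facets combine with AND, values within one facet with
OR. A tag facet value matches a Pixel Set tagged with that tag *or any
hierarchical descendant* of it. All text matching is case-insensitive
plain substring — no stemming, no regular expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .models import Pixel, PixelSet, TagPath
from .store import PixelStore

#: Number of equal-width histogram bins in a summary.
HISTOGRAM_BINS = 20


@dataclass(frozen=True)
class FilterSpec:
    """A faceted query; an all-empty spec matches every Pixel Set."""

    species: frozenset[str] | None = None
    omics_unit_types: frozenset[str] | None = None
    omics_areas: frozenset[str] | None = None
    tags: frozenset[TagPath] | None = None
    keyword: str | None = None

    @classmethod
    def build(
        cls,
        species=None,
        omics_unit_types=None,
        omics_areas=None,
        tags=None,
        keyword=None,
    ) -> "FilterSpec":
        def names(values):
            return None if not values else frozenset(values)

        return cls(
            species=names(species),
            omics_unit_types=names(omics_unit_types),
            omics_areas=names(omics_areas),
            tags=None if not tags else frozenset(TagPath.parse(t) for t in tags),
            keyword=keyword or None,
        )


def _fold(s: str) -> str:
    return s.casefold()


def _pixelset_facets(store: PixelStore, ps: PixelSet) -> dict:
    """Annotation values a Pixel Set exposes to the facet filter.

    Species and unit types come from the set's Pixels' Omics Units (a set
    measures one type in practice, but nothing enforces it), the area
    from its experiment.
    """
    units = {(p.omics_unit.strain.species.name, p.omics_unit.unit_type.name)
             for p in store.pixels(ps)}
    return {
        "species": {_fold(sp) for sp, _ in units},
        "unit_types": {_fold(ut) for _, ut in units},
        "area": _fold(ps.analysis.experiment.omics_area.name),
        "tags": ps.tags,
        "text": _fold(ps.analysis.description) + "\n"
        + _fold(ps.analysis.experiment.description),
    }


def matches(store: PixelStore, ps: PixelSet, spec: FilterSpec) -> bool:
    """Predicate underlying :func:`filter_pixelsets` (exposed for audit)."""
    f = _pixelset_facets(store, ps)
    if spec.species is not None:
        if not f["species"] & {_fold(s) for s in spec.species}:
            return False
    if spec.omics_unit_types is not None:
        if not f["unit_types"] & {_fold(t) for t in spec.omics_unit_types}:
            return False
    if spec.omics_areas is not None:
        if f["area"] not in {_fold(a) for a in spec.omics_areas}:
            return False
    if spec.tags is not None:
        ok = any(
            any(tag.is_descendant_or_self(want) for tag in f["tags"])
            for want in spec.tags
        )
        if not ok:
            return False
    if spec.keyword is not None:
        if _fold(spec.keyword) not in f["text"]:
            return False
    return True


def filter_pixelsets(store: PixelStore, spec: FilterSpec) -> list[PixelSet]:
    """All Pixel Sets satisfying every non-empty facet of ``spec``."""
    return [ps for ps in store.pixel_sets() if matches(store, ps, spec)]


# --------------------------------------------------------------------- #
# selection basket

class Selection:
    """An ordered, duplicate-free basket of Pixel Sets."""

    def __init__(self, pixel_sets: list[PixelSet] | None = None):
        self._sets: list[PixelSet] = []
        for ps in pixel_sets or []:
            self.add(ps)

    def add(self, pixel_set: PixelSet) -> "Selection":
        if pixel_set.uid not in {ps.uid for ps in self._sets}:
            self._sets.append(pixel_set)
        return self

    def remove(self, pixel_set: PixelSet) -> "Selection":
        self._sets = [ps for ps in self._sets if ps.uid != pixel_set.uid]
        return self

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __bool__(self) -> bool:
        return bool(self._sets)


# --------------------------------------------------------------------- #
# summaries

@dataclass(frozen=True)
class SummaryStats:
    """Distribution summary of one Pixel Set's values and quality scores."""

    n_pixels: int
    value_min: float | None
    value_max: float | None
    value_mean: float | None
    value_hist: tuple[int, ...]
    qs_min: float | None
    qs_max: float | None
    qs_mean: float | None
    qs_hist: tuple[int, ...]

    @property
    def defined(self) -> bool:
        """False when the set is empty and the means are undefined."""
        return self.n_pixels > 0


def _hist(data: np.ndarray) -> tuple[int, ...]:
    if data.size == 0:
        return tuple([0] * HISTOGRAM_BINS)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        hi = lo + 1.0  # single-valued data: everything in the first bin
    counts, _ = np.histogram(data, bins=HISTOGRAM_BINS, range=(lo, hi))
    return tuple(int(c) for c in counts)


def summarize_pixelset(store: PixelStore, pixel_set: PixelSet) -> SummaryStats:
    pixels = store.pixels(pixel_set)
    values = np.array([p.value for p in pixels], dtype=float)
    scores = np.array([p.quality_score for p in pixels], dtype=float)

    def stats(a: np.ndarray):
        if a.size == 0:
            return None, None, None
        return float(a.min()), float(a.max()), float(a.mean())

    vmin, vmax, vmean = stats(values)
    qmin, qmax, qmean = stats(scores)
    return SummaryStats(
        n_pixels=len(pixels),
        value_min=vmin, value_max=vmax, value_mean=vmean, value_hist=_hist(values),
        qs_min=qmin, qs_max=qmax, qs_mean=qmean, qs_hist=_hist(scores),
    )


# --------------------------------------------------------------------- #
# pixel-level keyword filtering

def filter_pixels_by_unit_keyword(
    store: PixelStore, selection: Selection, keyword: str
) -> dict[str, list[Pixel]]:
    """Per-set Pixels whose Omics Unit description contains ``keyword``.

    This is the exploration step that narrows a multi-omics comparison to
    units annotated with a function of interest (e.g. "pathogenesis").
    Keys are Pixel Set uids; per-set pixel order is preserved.
    """
    if not selection:
        raise ValidationError("selection is empty")
    if not keyword or not keyword.strip():
        raise ValidationError("keyword must be non-empty")
    needle = _fold(keyword)
    out: dict[str, list[Pixel]] = {}
    for ps in selection:
        out[ps.uid] = [
            p for p in store.pixels(ps) if needle in _fold(p.omics_unit.description)
        ]
    return out


# --------------------------------------------------------------------- #
# tabular export of query results

def export_query_results(store: PixelStore, pixel_sets: list[PixelSet]) -> bytes:
    """TSV listing of matching Pixel Sets with their annotations."""
    header = ["uid", "source_filename", "pixel_count", "omics_area",
              "analysis_description", "experiment_description", "tags"]
    lines = ["\t".join(header)]
    for ps in pixel_sets:
        lines.append("\t".join([
            ps.uid,
            ps.source_filename,
            str(ps.pixel_count),
            ps.analysis.experiment.omics_area.name,
            ps.analysis.description.replace("\t", " "),
            ps.analysis.experiment.description.replace("\t", " "),
            ",".join(sorted(str(t) for t in ps.tags)),
        ]))
    return ("\n".join(lines) + "\n").encode("utf-8")
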