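"""Faceted filtering, keyword search, selections and summaries."""

import itertools
import random

import numpy as np
import pytest

from pixelbase import (
    FilterSpec,
    FixtureParams,
    Selection,
    ValidationError,
    filter_pixels_by_unit_keyword,
    filter_pixelsets,
    generate_instance,
    run_import,
    summarize_pixelset,
)
from pixelbase.query import HISTOGRAM_BINS, matches
from pixelbase.models import TagPath


@pytest.fixture(scope="module")
def synthetic_store():
    store, archives = generate_instance(
        FixtureParams(n_units=30, n_pixel_sets=4, keyword_fraction=0.2, seed=5)
    )
    for i, z in enumerate(archives):
        run_import(store, z, tags={f"batch/{i}"})
    return store


class TestFacetedFilter:
    def test_case_study_tags_select_both_sets(self, imported_case_study):
        spec = FilterSpec.build(tags={"Candida glabrata", "alkaline pH"})
        assert len(filter_pixelsets(imported_case_study, spec)) == 2

    def test_empty_spec_matches_everything(self, synthetic_store):
        results = filter_pixelsets(synthetic_store, FilterSpec())
        assert len(results) == len(synthetic_store.pixel_sets())

    def test_facets_combine_with_and(self, imported_case_study):
        spec = FilterSpec.build(
            tags={"Candida glabrata"}, omics_areas={"RNA sequencing"}
        )
        results = filter_pixelsets(imported_case_study, spec)
        assert len(results) == 1
        assert results[0].source_filename == "Pixel_Set_A.txt"

    def test_tag_filter_includes_hierarchical_descendants(self, synthetic_store):
        # sets were tagged batch/<i>; filtering on the root "batch" finds all
        spec = FilterSpec.build(tags={"batch"})
        assert len(filter_pixelsets(synthetic_store, spec)) == len(
            synthetic_store.pixel_sets()
        )
        # batch/0 was applied to the first archive's two sets only
        spec = FilterSpec.build(tags={"batch/0"})
        assert len(filter_pixelsets(synthetic_store, spec)) == 2

    def test_keyword_searches_analysis_and_experiment_text(self, imported_case_study):
        hits = filter_pixelsets(imported_case_study, FilterSpec.build(keyword="LIMMA"))
        assert [ps.source_filename for ps in hits] == ["Pixel_Set_A.txt"]
        # keyword matching is case-insensitive substring
        hits = filter_pixelsets(imported_case_study, FilterSpec.build(keyword="limma"))
        assert len(hits) == 1

    def test_keyword_search_is_reflexive(self, synthetic_store):
        for ps in synthetic_store.pixel_sets():
            needle = ps.analysis.description[:20]
            hits = filter_pixelsets(synthetic_store, FilterSpec.build(keyword=needle))
            assert ps.uid in {h.uid for h in hits}

    def test_adding_a_facet_never_enlarges_results(self, synthetic_store):
        store = synthetic_store
        base_specs = {
            "species": {"Synthetica exemplaris"},
            "omics_unit_types": {"mRNA"},
            "omics_areas": {"RNA sequencing"},
            "tags": {"synthetic"},
            "keyword": "synthetic",
        }
        facet_names = list(base_specs)
        for r in range(len(facet_names) + 1):
            for combo in itertools.combinations(facet_names, r):
                spec = FilterSpec.build(**{k: base_specs[k] for k in combo})
                results = {ps.uid for ps in filter_pixelsets(store, spec)}
                for extra in set(facet_names) - set(combo):
                    narrowed = FilterSpec.build(
                        **{k: base_specs[k] for k in (*combo, extra)}
                    )
                    sub = {ps.uid for ps in filter_pixelsets(store, narrowed)}
                    assert sub <= results

    def test_agrees_with_exhaustive_predicate_scan(self, synthetic_store):
        """Independent brute force: re-derive each set's annotations from
        raw pixels and apply the documented facet semantics."""
        store = synthetic_store
        rng = random.Random(42)
        vocab_tags = ["synthetic", "set-1", "batch", "batch/2", "nope"]
        vocab_names = ["mRNA", "protein", "RNA sequencing", "Mass spectrometry",
                       "Synthetica exemplaris", "unknown"]
        for _ in range(25):
            spec = FilterSpec.build(
                species=rng.sample(vocab_names, rng.randint(0, 2)) or None,
                omics_unit_types=rng.sample(vocab_names, rng.randint(0, 2)) or None,
                omics_areas=rng.sample(vocab_names, rng.randint(0, 2)) or None,
                tags=rng.sample(vocab_tags, rng.randint(0, 2)) or None,
                keyword=rng.choice([None, "synthetic", "zzz"]),
            )
            expected = set()
            for ps in store.pixel_sets():
                pixels = store.pixels(ps)
                sp_names = {p.omics_unit.strain.species.name.lower() for p in pixels}
                ut_names = {p.omics_unit.unit_type.name.lower() for p in pixels}
                area = ps.analysis.experiment.omics_area.name.lower()
                text = (ps.analysis.description + "\n"
                        + ps.analysis.experiment.description).lower()
                ok = True
                if spec.species is not None:
                    ok &= bool(sp_names & {s.lower() for s in spec.species})
                if spec.omics_unit_types is not None:
                    ok &= bool(ut_names & {s.lower() for s in spec.omics_unit_types})
                if spec.omics_areas is not None:
                    ok &= area in {s.lower() for s in spec.omics_areas}
                if spec.tags is not None:
                    def descendant(t, w):
                        ts = str(t).lower().split("/")
                        ws = str(w).lower().split("/")
                        return ts[: len(ws)] == ws

                    ok &= any(
                        descendant(t, w) for t in ps.tags for w in spec.tags
                    )
                if spec.keyword is not None:
                    ok &= spec.keyword.lower() in text
                if ok:
                    expected.add(ps.uid)
            got = {ps.uid for ps in filter_pixelsets(store, spec)}
            assert got == expected


class TestSelection:
    def test_add_is_idempotent_and_ordered(self, imported_case_study):
        a, b = imported_case_study.pixel_sets()
        sel = Selection()
        sel.add(a).add(b).add(a)
        assert [ps.uid for ps in sel] == [a.uid, b.uid]
        assert len(sel) == 2

    def test_remove_then_re_add_moves_to_end(self, imported_case_study):
        a, b = imported_case_study.pixel_sets()
        sel = Selection([a, b])
        sel.remove(a)
        sel.add(a)
        assert [ps.uid for ps in sel] == [b.uid, a.uid]


class TestSummaries:
    def test_worked_example_summary(self, imported_case_study):
        store = imported_case_study
        ps_a = next(
            ps for ps in store.pixel_sets() if ps.source_filename == "Pixel_Set_A.txt"
        )
        stats = summarize_pixelset(store, ps_a)
        assert stats.n_pixels == 5
        assert stats.value_min == 0.30 and stats.value_max == 1.67
        assert stats.value_mean == pytest.approx(np.mean([1.09, 0.30, 0.90, 1.50, 1.67]))
        assert sum(stats.value_hist) == sum(stats.qs_hist) == 5

    def test_histogram_bins_sum_to_n_pixels_on_random_sets(self, synthetic_store):
        for ps in synthetic_store.pixel_sets():
            stats = summarize_pixelset(synthetic_store, ps)
            assert len(stats.value_hist) == HISTOGRAM_BINS
            assert sum(stats.value_hist) == stats.n_pixels
            assert sum(stats.qs_hist) == stats.n_pixels
            assert stats.defined

    def test_empty_set_flags_undefined_means(self, imported_case_study):
        store = imported_case_study
        from pixelbase.models import Analysis, Experiment, FileRef, Pixeler

        exp = store.add_experiment(
            Experiment("empty exp", store.get_omics_area("RNA sequencing"))
        )
        pxr = store.add_pixeler(Pixeler("nobody"))
        ref = FileRef("f", "0" * 32)
        an = store.add_analysis(Analysis("empty an", exp, ref, ref, pxr))
        ps = store.add_pixel_set("empty.txt", an)
        stats = summarize_pixelset(store, ps)
        assert stats.n_pixels == 0
        assert not stats.defined
        assert stats.value_mean is None and stats.qs_mean is None


class TestUnitKeywordFilter:
    def test_pathogenesis_on_worked_example_keeps_all_pixels(self, imported_case_study):
        store = imported_case_study
        sel = Selection(store.pixel_sets())
        grouped = filter_pixels_by_unit_keyword(store, sel, "pathogenesis")
        assert [len(v) for v in grouped.values()] == [5, 5]

    def test_absent_keyword_keeps_nothing(self, imported_case_study):
        store = imported_case_study
        sel = Selection(store.pixel_sets())
        grouped = filter_pixels_by_unit_keyword(store, sel, "flux capacitor")
        assert all(v == [] for v in grouped.values())

    def test_matching_is_case_insensitive_substring(self, imported_case_study):
        store = imported_case_study
        sel = Selection(store.pixel_sets())
        grouped = filter_pixels_by_unit_keyword(store, sel, "PATHOGEN")
        assert [len(v) for v in grouped.values()] == [5, 5]

    def test_empty_selection_or_keyword_rejected(self, imported_case_study):
        store = imported_case_study
        with pytest.raises(ValidationError):
            filter_pixels_by_unit_keyword(store, Selection(), "x")
        with pytest.raises(ValidationError):
            filter_pixels_by_unit_keyword(
                store, Selection(store.pixel_sets()), "  "
            )


class TestTagSemantics:
    @pytest.mark.parametrize(
        "tag,flt,expected",
        [
            ("a/b/c", "a", True),
            ("a/b/c", "A/B", True),  # case-insensitive
            ("a/b/c", "a/b/c", True),
            ("a", "a/b", False),  # ancestors do not match a deeper filter
            ("ab", "a", False),  # prefix is per-segment, not per-character
        ],
    )
    def test_descendant_matching(self, tag, flt, expected):
        assert TagPath.parse(tag).is_descendant_or_self(TagPath.parse(flt)) is expected
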