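"""Submission state machine: ordering, validation failures, atomicity."""

import pytest

from pixelbase import (
    ArchiveError,
    PixelbaseError,
    StateError,
    ValidationError,
    corrupt_archive,
    new_session,
    run_import,
)
from pixelbase.archive import (
    AnalysisMeta,
    ExperimentMeta,
    FileRef,
    PixelSetDeclaration,
    PixelerMeta,
    SubmissionMeta,
    write_archive,
    write_pixelset_file,
    PixelRecord,
)
from pixelbase.fixtures import CASE_STUDY_GENES, case_study_fixture
from pixelbase.workflow import SessionState


def snapshot(store):
    return store.counts(), store.content_digest()


def two_set_archive():
    """One archive bundling the mRNA and protein worked-example files."""
    recs_a = [PixelRecord(g, v, qs) for g, _, v, qs, _, _ in CASE_STUDY_GENES]
    recs_b = [PixelRecord(g, v, qs) for g, _, _, _, v, qs in CASE_STUDY_GENES]
    files = {
        "setA.txt": write_pixelset_file(recs_a),
        "setB.txt": write_pixelset_file(recs_b),
        "secondary.tsv": b"id\tcount\n",
        "nb.Rmd": b"# nb\n",
    }
    decl = lambda fn, ut: PixelSetDeclaration(
        fn, "0" * 32, ut, "ATCC2001", "Candida glabrata", f"{ut} set"
    )
    meta = SubmissionMeta(
        experiment=ExperimentMeta("pH shift", "RNA sequencing"),
        analysis=AnalysisMeta(
            "combined analysis", FileRef("secondary.tsv", "0" * 32),
            FileRef("nb.Rmd", "0" * 32),
        ),
        pixeler=PixelerMeta("someone"),
        declarations=(decl("setA.txt", "mRNA"), decl("setB.txt", "protein")),
    )
    return write_archive(meta, files)


class TestHappyPath:
    def test_two_files_of_five_rows_import_as_2_sets_10_pixels(self, case_study):
        store, _, _ = case_study
        result = run_import(store, two_set_archive())
        assert (result.pixel_sets_created, result.pixels_created) == (2, 10)

    def test_session_walks_all_states(self, case_study):
        store, a, _ = case_study
        s = new_session()
        assert s.state is SessionState.CREATED
        s.attach_archive(a)
        assert s.state is SessionState.UPLOADED
        report = s.run_meta_checks(store)
        assert s.state is SessionState.META_CHECKED
        assert report.ok and not any(report.missing_units.values())
        s.confirm_annotation(store)
        assert s.state is SessionState.ANNOTATED
        s.assign_tags({"Candida glabrata", "alkaline pH", "WT", "logFC"})
        assert s.state is SessionState.TAGGED
        assert len(s.pending_tags) == 4
        result = s.finalize(store)
        assert s.state is SessionState.IMPORTED
        assert result.pixels_created == 5

    def test_tags_step_is_optional(self, case_study):
        store, a, _ = case_study
        s = new_session()
        s.attach_archive(a)
        s.run_meta_checks(store)
        s.confirm_annotation(store)
        result = s.finalize(store)  # annotated -> imported directly
        assert result.pixel_sets_created == 1

    def test_workbook_and_session_tags_are_unioned(self, case_study):
        store, a, _ = case_study  # archives declare the 4 case-study tags
        s = new_session()
        s.attach_archive(a)
        s.run_meta_checks(store)
        s.confirm_annotation(store)
        s.assign_tags({"extra/tag"})
        result = s.finalize(store)
        ps = store.get_pixel_set(result.pixel_set_uids[0])
        assert {str(t) for t in ps.tags} == {
            "Candida glabrata", "alkaline pH", "WT", "logFC", "extra/tag",
        }


class TestStateMachineGuards:
    def test_out_of_order_calls_raise_without_mutating(self, case_study):
        store, a, _ = case_study
        s = new_session()
        with pytest.raises(StateError):
            s.run_meta_checks(store)
        with pytest.raises(StateError):
            s.finalize(store)
        assert s.state is SessionState.CREATED
        s.attach_archive(a)
        with pytest.raises(StateError):
            s.attach_archive(a)  # second attach on the same session
        assert s.state is SessionState.UPLOADED

    def test_replay_finalize_is_rejected_and_counts_stable(self, case_study):
        store, a, _ = case_study
        s = new_session()
        s.attach_archive(a)
        s.run_meta_checks(store)
        s.confirm_annotation(store)
        s.finalize(store)
        before = snapshot(store)
        with pytest.raises(StateError):
            s.finalize(store)
        assert snapshot(store) == before

    def test_malformed_tag_is_a_validation_error(self, case_study):
        store, a, _ = case_study
        s = new_session()
        s.attach_archive(a)
        s.run_meta_checks(store)
        s.confirm_annotation(store)
        from pixelbase.models import TagPath

        with pytest.raises(ValidationError):
            s.assign_tags({TagPath(("bad/segment",))})


class TestFailurePaths:
    def test_corrupt_zip_fails_without_touching_store(self, case_study):
        store, _, _ = case_study
        before = snapshot(store)
        s = new_session()
        with pytest.raises(ArchiveError):
            s.attach_archive(b"not a zip at all")
        assert s.state is SessionState.FAILED
        assert snapshot(store) == before

    def test_unregistered_unit_reports_the_full_missing_list(self, case_study):
        store, a, _ = case_study
        recs = [PixelRecord(g, v, qs) for g, _, v, qs, _, _ in CASE_STUDY_GENES]
        recs.append(PixelRecord("CAGL0_FAKE", 1.0, 0.5))
        files = {
            "setA.txt": write_pixelset_file(recs),
            "secondary.tsv": b"id\n",
            "nb.Rmd": b"#\n",
        }
        meta = SubmissionMeta(
            experiment=ExperimentMeta("pH shift", "RNA sequencing"),
            analysis=AnalysisMeta(
                "x", FileRef("secondary.tsv", "0" * 32), FileRef("nb.Rmd", "0" * 32)
            ),
            pixeler=PixelerMeta("someone"),
            declarations=(
                PixelSetDeclaration(
                    "setA.txt", "0" * 32, "mRNA", "ATCC2001", "Candida glabrata"
                ),
            ),
        )
        s = new_session()
        s.attach_archive(write_archive(meta, files))
        before = snapshot(store)
        with pytest.raises(ValidationError, match="CAGL0_FAKE"):
            s.run_meta_checks(store)
        assert s.state is SessionState.FAILED
        assert snapshot(store) == before

    def test_tampered_file_fails_with_checksum_mismatch(self, case_study):
        store, a, _ = case_study
        s = new_session()
        s.attach_archive(corrupt_archive(a, "flip_byte", seed=1))
        before = snapshot(store)
        with pytest.raises(ValidationError, match="checksum"):
            s.run_meta_checks(store)
        assert s.state is SessionState.FAILED
        assert snapshot(store) == before

    def test_unknown_annotation_name_fails_naming_the_field(self):
        # store registered with mass spectrometry only; archive declares
        # an RNA sequencing experiment
        from pixelbase import PixelStore

        full_store, a, _ = case_study_fixture()
        store = PixelStore()
        sp = store.register_species("Candida glabrata")
        store.register_strain("ATCC2001", sp)
        store.register_omics_unit_type("mRNA")
        store.register_omics_area("Mass spectrometry")
        for g, d, *_ in CASE_STUDY_GENES:
            store.register_omics_unit(g, d, "http://x", "ATCC2001", "mRNA")
        s = new_session()
        s.attach_archive(a)
        s.run_meta_checks(store)
        before = snapshot(store)
        with pytest.raises(ValidationError, match="omics_area"):
            s.confirm_annotation(store)
        assert s.state is SessionState.FAILED
        assert snapshot(store) == before  # staging never persists

    def test_injected_failure_mid_transaction_rolls_back(self, case_study):
        store, a, _ = case_study
        s = new_session()
        s.attach_archive(a)
        s.run_meta_checks(store)
        s.confirm_annotation(store)
        before = snapshot(store)

        def boom():
            raise RuntimeError("injected persistence failure")

        with pytest.raises(RuntimeError):
            s.finalize(store, _failpoint=boom)
        assert s.state is SessionState.FAILED
        assert snapshot(store) == before


class TestConservation:
    def test_pixels_created_equals_parsed_rows(self, case_study):
        store, a, b = case_study
        from pixelbase.archive import parse_pixelset_file, read_archive

        for z in (a, b):
            bundle = read_archive(z)
            rows = sum(
                len(parse_pixelset_file(bundle.files[d.filename]))
                for d in bundle.meta.declarations
            )
            assert run_import(store, z).pixels_created == rows
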