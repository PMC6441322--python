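import pytest

from pixelbase import case_study_fixture, run_import


@pytest.fixture()
def case_study():
    """(pre-registered store, archive A bytes, archive B bytes)."""
    return case_study_fixture()


@pytest.fixture()
def imported_case_study(case_study):
    """Store with both worked-example Pixel Sets already imported."""
    store, a, b = case_study
    run_import(store, a)
    run_import(store, b)
    return store
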