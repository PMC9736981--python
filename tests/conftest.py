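import pytest
from hypothesis import settings

import biotransid as bt

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return bt.load_reaction_library()


@pytest.fixture(scope="session")
def fixture_rows():
    return bt.load_fixture()


@pytest.fixture(scope="session")
def annotator():
    return bt.MetaboliteAnnotator(bt.PARENT_FORMULA)


@pytest.fixture(scope="session")
def candidates(annotator):
    return annotator.candidates()


@pytest.fixture(scope="session")
def candidate_mzs(candidates):
    """All candidate ion masses — the decoy keep-out list for true negatives."""
    return [mz for c in candidates for mz in c.theoretical_mz.values()]


@pytest.fixture(scope="session")
def clean_run(fixture_rows):
    """Jitter-free, decoy-free synthetic run."""
    config = bt.SyntheticRunConfig(jitter_ppm=0.0, decoy_count_per_matrix=0, seed=0)
    return bt.generate_run(fixture_rows, config)


@pytest.fixture(scope="session")
def clean_result(annotator, clean_run):
    peaks, spectra = clean_run
    return annotator.annotate(peaks, spectra, consolidate_by="feature_id")
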