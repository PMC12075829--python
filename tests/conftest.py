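import pytest

from cdftscreen import datasets


@pytest.fixture(scope="session")
def bundle():
    """Bundled reference dataset, loaded once per session."""
    return datasets.load_study_bundle()


@pytest.fixture(scope="session")
def candidates(bundle):
    return datasets.candidate_table(bundle)
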