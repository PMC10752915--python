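import pytest

from ddtcf.cohort import load_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 18-sample pLGG cohort table, parsed once per session."""
    return load_reference_cohort()
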