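import pytest

from gciplpower import load_pilot_cohort


@pytest.fixture(scope="session")
def pilot():
    """The packaged five-eye pilot cohort."""
    return load_pilot_cohort()
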