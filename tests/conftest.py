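import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")

from apbi_cea import builtin_table1


@pytest.fixture(scope="session")
def bundle():
    """Bundled published parameter sets with calibrated conventions."""
    return builtin_table1()
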