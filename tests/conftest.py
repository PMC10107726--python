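import pytest

from iredmine.motifs import default_patterns
from iredmine.synth import reference_record


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


@pytest.fixture(scope="session")
def ref():
    return reference_record()
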