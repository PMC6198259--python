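import pytest

from agepop.casestudies import worked_example
from agepop.simulate import run


@pytest.fixture(scope="session")
def worked_example_det():
    """Deterministic hourly run of the periodic-development worked example."""
    return run(worked_example())
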