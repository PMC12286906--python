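import pytest
from hypothesis import settings

from demcea import base_case_parameters

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_params():
    """The packaged base-case parameter bundle (calibrated conventions)."""
    return base_case_parameters()
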