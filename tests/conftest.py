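import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from bpmpra import SpliceModelParams, generate_library  # noqa: E402


@pytest.fixture(scope="session")
def small_library():
    return generate_library(60, seed=7)


@pytest.fixture()
def mutant_params():
    return SpliceModelParams(lambda_minus1=0.4)
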