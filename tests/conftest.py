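import pytest
from hypothesis import settings

from ecnle import MATERIALS, FluidState, compute_structure

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def structure_055():
    return compute_structure(0.55)


@pytest.fixture(scope="session")
def state_055():
    return FluidState(0.55)


@pytest.fixture(scope="session")
def curcumin():
    return MATERIALS["curcumin"]
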