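import pytest

from nbudget import load_registry
from nbudget.budget import load_reference_flows


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def reference_network():
    return load_reference_flows(2018)
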