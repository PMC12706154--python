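import pytest

from startrac import default_registry, parse_diplotype


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def panel(registry):
    return registry.panel


def diplotype(label):
    return parse_diplotype(label)
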