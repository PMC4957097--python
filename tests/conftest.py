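import pytest

from turgorkit.io import load_mixture_file
from turgorkit.mixtures import OsmoticModelParams


@pytest.fixture(scope="session")
def params():
    return OsmoticModelParams()


@pytest.fixture(scope="session")
def fixture_entries():
    """Packaged mixture definitions with reference measurements."""
    return load_mixture_file()


@pytest.fixture(scope="session")
def mixtures(fixture_entries):
    return {e["mixture"].name: e["mixture"] for e in fixture_entries}


@pytest.fixture(scope="session")
def measured(fixture_entries):
    return {e["mixture"].name: e["measured_MPa"] for e in fixture_entries}
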