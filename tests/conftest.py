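import pytest

from oleaflux.toy import build_toy_gem


@pytest.fixture(scope="session")
def toy():
    """Default toy model + manifest, built once; tests copy before mutating."""
    return build_toy_gem()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_manifest(toy):
    return toy[1]
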