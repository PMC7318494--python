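import pytest

from kdrtyper import default_panel, enumerate_genotypes


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def genotypes27(panel):
    return enumerate_genotypes(panel)
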