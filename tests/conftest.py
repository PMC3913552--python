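import pytest

from fusionscreen.fixtures import default_fusion_forms


@pytest.fixture(scope="session")
def models_and_forms():
    """Session-wide fixture gene models: donor, acceptor, and the three
    candidate fusion forms (donor exon 2 | acceptor exon 3/4/5, k=20)."""
    return default_fusion_forms()


@pytest.fixture(scope="session")
def donor(models_and_forms):
    return models_and_forms[0]


@pytest.fixture(scope="session")
def acceptor(models_and_forms):
    return models_and_forms[1]


@pytest.fixture(scope="session")
def forms(models_and_forms):
    return models_and_forms[2]
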