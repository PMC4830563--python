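import pytest

from pseudoscan import make_reference


@pytest.fixture(scope="session")
def model():
    """The default 13-exon reference gene (1815-nt CDS)."""
    return make_reference(1)


@pytest.fixture(scope="session")
def control_model():
    """An unrelated intact gene standing in for a control paralog."""
    return make_reference(999, gene_id="control")
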