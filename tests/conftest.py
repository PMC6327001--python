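import pytest

from fcgrkit import synthetic


@pytest.fixture(scope="session")
def model():
    """The bundled FCGR2A-scale synthetic gene model."""
    return synthetic.fcgr2a_like()


@pytest.fixture(scope="session")
def family():
    """Synthetic receptor-family stand-in panel."""
    return synthetic.simulate_receptor_family(seed=0)
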