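import pytest

from photophys.fixtures import make_fixtures


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """A full noiseless synthetic input tree for T. oceanica."""
    d = tmp_path_factory.mktemp("fx")
    truth = make_fixtures(d, seed=11, species="T_oceanica")
    return d, truth
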