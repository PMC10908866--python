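import pytest

from mtdyn import load_mtbd_sequence, load_reference_library
from mtdyn.fixtures import make_fixtures
from mtdyn.synth import generate_shift_table


@pytest.fixture(scope="session")
def sequence():
    return load_mtbd_sequence()


@pytest.fixture(scope="session")
def library():
    return load_reference_library()


@pytest.fixture(scope="session")
def shift_table(sequence, library):
    return generate_shift_table(sequence, library, seed=3)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "bundle"
    make_fixtures(11, out)
    return out


@pytest.fixture(scope="session")
def noiseless_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures_nl") / "bundle"
    make_fixtures(11, out, noiseless=True)
    return out
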