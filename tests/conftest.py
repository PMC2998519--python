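import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pathnet import FixtureParams, builtin_fixture, generate_repository, load_repository


@pytest.fixture(scope="session")
def atp_doc():
    return builtin_fixture("atp_localization")


@pytest.fixture()
def atp_repo(atp_doc):
    return load_repository(atp_doc)


@pytest.fixture()
def chain_repo():
    return load_repository(builtin_fixture("chain"))


@pytest.fixture()
def cycle_repo():
    return load_repository(builtin_fixture("cycle"))


@pytest.fixture()
def clutter_repo():
    return load_repository(builtin_fixture("clutter"))


@pytest.fixture()
def hormone_repo():
    return load_repository(builtin_fixture("hormone_pair"))


@pytest.fixture(scope="session")
def rand_doc():
    """The canonical random fixture: seed 42, 20 pathways."""
    return generate_repository(FixtureParams(seed=42, n_pathways=20))


@pytest.fixture()
def rand_repo(rand_doc):
    return load_repository(rand_doc)


@pytest.fixture(scope="session")
def empty_doc():
    from pathnet.schema import COLLECTIONS, FORMAT_VERSION

    doc = {"format_version": FORMAT_VERSION}
    for name in COLLECTIONS:
        doc[name] = []
    return doc
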