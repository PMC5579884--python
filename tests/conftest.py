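import pytest

import labweed as lw


@pytest.fixture(scope="session")
def db():
    return lw.default_database()


@pytest.fixture(scope="session")
def field(db):
    return db.surface("Arable land")


@pytest.fixture(scope="session")
def grey_pavings(db):
    return db.surface("Grey paving stones")


@pytest.fixture(scope="session")
def grassland(db):
    return db.surface("Grassland")


@pytest.fixture(scope="session")
def green1(db):
    return db.green("Green 1")
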