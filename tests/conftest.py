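import pytest

from pephelix import datasets as ds
from pephelix.random_coil import wishart1995


@pytest.fixture(scope="session")
def cb1():
    return ds.CB1_391_409


@pytest.fixture(scope="session")
def barr1():
    return ds.BARR1_63_76


@pytest.fixture(scope="session")
def rc():
    return wishart1995()
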