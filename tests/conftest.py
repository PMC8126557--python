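import pytest

from regamp import run_census


@pytest.fixture(scope="session")
def cubic12_census():
    return run_census(order=12, degree=3)


@pytest.fixture(scope="session")
def cubic14_census():
    return run_census(order=14, degree=3)


@pytest.fixture(scope="session")
def cubic16_census():
    return run_census(order=16, degree=3)


@pytest.fixture(scope="session")
def quartic11_census():
    return run_census(order=11, degree=4)
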