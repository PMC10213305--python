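import pytest
from hypothesis import settings

from tsmr import builtin_fixture, harmonize, orient_positive_exposure

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chinese_tables():
    return builtin_fixture("chinese")


@pytest.fixture(scope="session")
def japanese_tables():
    return builtin_fixture("japanese")


@pytest.fixture(scope="session")
def chinese_set(chinese_tables):
    hset, log = harmonize(*chinese_tables)
    assert not log
    return orient_positive_exposure(hset)


@pytest.fixture(scope="session")
def japanese_set(japanese_tables):
    hset, log = harmonize(*japanese_tables)
    assert not log
    return orient_positive_exposure(hset)
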