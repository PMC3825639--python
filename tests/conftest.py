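import pytest

from fieldml import library, toolkit


@pytest.fixture(scope="session")
def lib():
    return library.load_library()


@pytest.fixture(scope="session")
def example():
    """The two-element / six-node worked model with its manifest."""
    return toolkit.build_illustrative_example()


@pytest.fixture()
def real(lib):
    return lib.types["real.1d"]
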