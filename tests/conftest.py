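import pytest

from pepfunnel import bundled_reference, bundled_screening_pool


@pytest.fixture(scope="session")
def reference():
    """The bundled 37-entry known-bioactive-peptide table."""
    return bundled_reference()


@pytest.fixture()
def screening_pool():
    """The bundled 15-peptide binding-filter-survivor pool (fresh copy)."""
    return bundled_screening_pool()
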