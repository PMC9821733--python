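import pytest

from seqforge import library_design as ld


@pytest.fixture(scope="session")
def design() -> ld.LibraryDesign:
    """The packaged default sequestrin library design."""
    return ld.load_design()


@pytest.fixture(scope="session")
def naive_pool(design):
    """A 2000-clone pool sampled from the default design (fixed seed)."""
    return ld.sample_clones(design, 2000, seed=20230103)
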