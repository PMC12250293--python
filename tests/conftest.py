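import pytest

from paralogmeth.synthetic import exon2_like_fixture, generate_melt_standards


@pytest.fixture(scope="session")
def duplex_fixture():
    """The shipped synthetic duplex preset: (pair, truth, assay config)."""
    return exon2_like_fixture()


@pytest.fixture(scope="session")
def duplex_positions(duplex_fixture):
    from paralogmeth.assay import map_dispensation_positions
    _, _, config = duplex_fixture
    return map_dispensation_positions(config)


@pytest.fixture(scope="session")
def melt_standards():
    """Noise-free melt curves for the 0/25/50/75% standard series."""
    return generate_melt_standards()
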