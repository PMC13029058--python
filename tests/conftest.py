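import pytest

from phagemine.simulate import (
    generate_phage_contig,
    make_seed_capsid,
    make_seed_rnap,
)


@pytest.fixture(scope="session")
def seed_rnap():
    return make_seed_rnap()


@pytest.fixture(scope="session")
def seed_capsid():
    return make_seed_capsid()


@pytest.fixture(scope="session")
def planted_contig():
    """A synthetic contig with 14 planted promoter instances, one ssRNAP
    gene at 55 % target identity, and one capsid gene (read-only)."""
    return generate_phage_contig(seed=3)
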