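import pytest

from loxkit.genome_model import LUArrangement, generate_fixture
from loxkit.tag_design import DesignParams, design_tags


@pytest.fixture(scope="session")
def small_chrom():
    """3 LUs of exactly 600 bp — small enough for exhaustive design oracles."""
    return generate_fixture(3, (600, 600), seed=42)


@pytest.fixture(scope="session")
def std_chrom():
    """The standard fixture: 12 LUs of 1.5-2.5 kb, linear, so a 1000 bp
    amplicon can never bridge a whole LU."""
    return generate_fixture(12, (1500, 2500), seed=1)


@pytest.fixture(scope="session")
def std_panel(std_chrom):
    return design_tags(std_chrom)


@pytest.fixture(scope="session")
def small_panel(small_chrom):
    return design_tags(small_chrom)


@pytest.fixture(scope="session")
def circ_chrom():
    return generate_fixture(6, (800, 1200), topology="circular", seed=3)


@pytest.fixture(scope="session")
def circ_panel(circ_chrom):
    return design_tags(circ_chrom)


@pytest.fixture()
def identity(std_chrom):
    return LUArrangement.identity(std_chrom)
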