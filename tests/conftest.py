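import io

import pytest

from coiaudit.records import read_genbank
from coiaudit.simulate import SyntheticConfig, SyntheticData, generate


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=42, year_start=2003, year_end=2006,
                           base_deposits=40, annual_growth=0.5)


@pytest.fixture(scope="session")
def small_data(small_config) -> SyntheticData:
    return generate(small_config)


@pytest.fixture(scope="session")
def small_recordset(small_data):
    """The small synthetic set re-read through the flatfile parser."""
    return read_genbank(io.StringIO(small_data.genbank_text))


@pytest.fixture(scope="session")
def big_data() -> SyntheticData:
    """~20k records for statistical parameter-recovery checks."""
    config = SyntheticConfig(
        seed=7, year_start=2003, year_end=2007, base_deposits=1520,
        annual_growth=0.5, p_full=0.5, p_barcode=0.0,
        p_country=0.74, p_latlon=0.51, length_fixed=650,
    )
    return generate(config)
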