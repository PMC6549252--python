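import pytest

from allopatry import (
    NINE_STRAIN_PLATES,
    SiteRecord,
    SiteTable,
    packaged_fixtures,
)

EUROPEAN_CLADE = ["SolV", "Fur", "Rib", "Fdl", "Ice"]
SIX_NEW_ISOLATES = ["Fur", "Rib", "Fdl", "Ice", "Yel", "Phi"]
AZORES = ["Fur", "Rib", "Fdl"]


@pytest.fixture(scope="session")
def fixtures():
    return packaged_fixtures()


@pytest.fixture(scope="session")
def site_table(fixtures):
    return fixtures["site_table"]


@pytest.fixture(scope="session")
def ddh(fixtures):
    return fixtures["ddh_matrix"]


@pytest.fixture(scope="session")
def s16(fixtures):
    return fixtures["s16_matrix"]


@pytest.fixture(scope="session")
def nine_strain_plate_table(ddh):
    """All nine strains with their tectonic-plate assignments (no coordinates
    for SolV/V4/Kam1 — the sympatry analysis does not need them)."""
    return SiteTable(
        SiteRecord(name=name, plate=NINE_STRAIN_PLATES[name]) for name in ddh.labels
    )
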