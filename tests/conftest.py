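import pytest

from xylemtrn.catalog import CatalogEntry, GeneCatalog
from xylemtrn.motifs import default_motifs


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture()
def small_catalog():
    return GeneCatalog(
        [
            CatalogEntry("WND1", "chr1", "+", 10_000, "WND", "NAC"),
            CatalogEntry("TF_NAC1", "chr1", "+", 20_000, "TF", "NAC",
                         frozenset({"NAC072_class"})),
            CatalogEntry("TF_MYB1", "chr1", "-", 30_000, "TF", "MYB"),
            CatalogEntry("TF_WRKY1", "chr1", "+", 40_000, "TF", "WRKY"),
            CatalogEntry("TF_OTHER1", "chr1", "-", 50_000, "TF", "other"),
            CatalogEntry("CW1", "chr1", "+", 60_000, "CW_secondary"),
            CatalogEntry("CW2", "chr1", "-", 70_000, "CW_primary"),
            CatalogEntry("PCD1", "chr1", "+", 80_000, "PCD"),
            CatalogEntry("BG1", "chr1", "-", 90_000, "background"),
        ]
    )
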