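import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from musadiv.io_formats import BandMatrix, LocusId

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def hand_matrix() -> BandMatrix:
    """Five genotypes, two primers (one RAPD, one ISSR), one missing cell."""
    loci = [
        LocusId("OPC-08", "RAPD", "500"),
        LocusId("OPC-08", "RAPD", "750"),
        LocusId("OPC-08", "RAPD", "1000"),
        LocusId("UBC-810", "ISSR", "300"),
        LocusId("UBC-810", "ISSR", "600"),
    ]
    values = np.array(
        [
            [1, 1, 0, 1, 0],
            [1, 0, 1, 1, 0],
            [0, 1, 1, 0, 1],
            [1, 1, 1, np.nan, 1],
            [0, 0, 1, 1, 1],
        ],
        dtype=float,
    )
    return BandMatrix(["Ga", "Gb", "Gc", "Gd", "Ge"], loci, values)


@pytest.fixture(scope="session")
def volatile_table():
    from musadiv.volatilome import packaged_volatile_table

    return packaged_volatile_table()
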