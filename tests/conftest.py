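import numpy as np
import pytest

from rtgrecomb.markers import Chromosome, MarkerMap
from rtgrecomb.simulate import SimConfig, make_marker_map


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two small chromosomes; fast to simulate, still arm-structured."""
    return SimConfig(
        chromosomes=[
            Chromosome("chr1", 600_000, 300_000, 300_200),
            Chromosome("chr2", 400_000, 150_000, 150_200),
        ]
    )


@pytest.fixture(scope="session")
def small_map(small_config) -> MarkerMap:
    return make_marker_map(small_config, seed=1)


@pytest.fixture()
def toy_map() -> MarkerMap:
    """Ten evenly spaced markers on one chromosome, centromere in the middle."""
    chrom = Chromosome("chrT", 11_000, 5_400, 5_600)
    pos = np.array([500, 1500, 2500, 3500, 4500, 6500, 7500, 8500, 9500, 10_500])
    return MarkerMap([chrom], np.zeros(10, dtype=np.int32), pos)
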