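import numpy as np
import pytest

from anchorfill.simulate import SatelliteSpec, SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """One shared ground-truth bundle under the default study conditions."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def chip_bundle():
    """Bundle with satellite blocks a minor share of the library, so the
    planted ChIP preference is recoverable as an enrichment ratio."""
    return simulate(
        SimulationConfig(
            seed=5,
            unique_segment_length=100_000,
            satellite=SatelliteSpec(copies_per_cluster=30),
            chip_reads_per_sample=50_000,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture()
def make_dna(rng):
    def _make(length, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return random_dna(r, length)

    return _make
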