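import numpy as np
import pytest

from perioscan import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def genbank_fixture_path(tmp_path_factory):
    """Synthetic 30 kb annotated GenBank record with a planted 11 bp region."""
    path = tmp_path_factory.mktemp("gb") / "synthetic_fixture.gb"
    fixtures.make_genbank_fixture(path, seed=7)
    return path


@pytest.fixture(scope="session")
def planted_sequence():
    """50 kb sequence fully phased at 10.5 bp (AA tracts, density 1)."""
    spec = fixtures.PlantedPeriodicitySpec(
        length=50_000, period=10.5, tract="AA", density=1.0, jitter=0, seed=11
    )
    return fixtures.plant_periodicity(spec)


def random_sequence(rng, length, freqs=(0.25, 0.25, 0.25, 0.25)):
    return fixtures.bernoulli_sequence(length, freqs, rng=rng)
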