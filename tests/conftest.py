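import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from seedshadow.core import Genotype, Location, PlantRecord
from seedshadow.synthetic import (
    generate_genotypes,
    generate_landscape,
    parkia_like,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def parkia_cfg():
    return parkia_like(seed=7)


@pytest.fixture(scope="session")
def parkia_system(parkia_cfg):
    """A small fully generated study system shared across tests."""
    adults, polygon = generate_landscape(parkia_cfg, 7)
    true_g, obs_g, freqs = generate_genotypes(adults, parkia_cfg, 8)
    return {
        "cfg": parkia_cfg,
        "adults": adults,
        "polygon": polygon,
        "true_genotypes": true_g,
        "observed_genotypes": obs_g,
        "freqs": freqs,
    }


def make_genotype(sample_id, calls, loci=None):
    loci = loci or tuple(f"L{i:02d}" for i in range(len(calls)))
    return Genotype(sample_id=sample_id, loci=tuple(loci), calls=tuple(calls))
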