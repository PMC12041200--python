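import numpy as np
import pytest
from hypothesis import settings

import evtsar as e

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def triphasic_community():
    """Small community with uniform centres spanning all three phases."""
    cfg = e.CommunityConfig(n_species=2000, n_individuals=200, sigma_kernel=1.0,
                            region_radius=20.0, seed=5)
    return e.generate_community(cfg)


@pytest.fixture(scope="session")
def triphasic_curve(triphasic_community):
    return e.simulate_sar_realisation(triphasic_community, n=200, seed=6)


@pytest.fixture(scope="session")
def gaussian_fixture_table():
    """Occurrence table of clustered Gaussian species, no aggregation artefact."""
    cfg = e.CommunityConfig(n_species=30, n_individuals=1000, sigma_kernel=2.0,
                            region_radius=15.0, seed=9)
    return e.generate_occurrence_fixture(cfg, aggregation_fraction=0.0)
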