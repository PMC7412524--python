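import numpy as np
import pytest

from hivesim import SchemeConfig, Simulation, TraitArchitecture, sample_architecture

MODERATE = (1.0, 2.0, -0.75)  # sigma_m2, sigma_d2, sigma_md -> r_md = -0.53
STRONG = (1.0, 2.0, -1.25)  # r_md = -0.88


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def arch(rng) -> TraitArchitecture:
    """Small 60-locus architecture with the standard moderate-correlation trait."""
    return sample_architecture(60, MODERATE, 1.0, rng)


@pytest.fixture
def arch200(rng) -> TraitArchitecture:
    """Full-size 200-locus architecture."""
    return sample_architecture(200, MODERATE, 1.0, rng)


@pytest.fixture
def small_run(arch):
    """A short small-population run shared by several structural tests."""
    cfg = SchemeConfig(n_queens=30, sister_group_size=3, sire_rate_percent=10, years=12)
    sim = Simulation(cfg, arch, 123)
    res = sim.run()
    return sim, res
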