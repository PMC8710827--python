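import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from wgdkit.simulate import WGDScenario, simulate_wgd_genome  # noqa: E402


@pytest.fixture(scope="session")
def lossless_sim():
    """Small lossless one-extra-WGD scenario shared across synteny/WGD tests."""
    scenario = WGDScenario(n_chromosomes=2, genes_per_chromosome=60,
                           retention_prob=1.0, seed=11)
    focal, reference, truth = simulate_wgd_genome(scenario)
    return scenario, focal, reference, truth


@pytest.fixture(scope="session")
def lossless_hits(lossless_sim):
    from wgdkit import find_homologs

    _, focal, reference, _ = lossless_sim
    return find_homologs(reference.proteins, focal.proteins)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
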