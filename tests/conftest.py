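import pytest

from talscan.pipeline import analyze_genome
from talscan.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded zero-noise cohort exercising all four morphotypes."""
    genomes, truth = simulate_cohort(SimConfig(n_genomes=12, seed=42))
    return genomes, truth


@pytest.fixture(scope="session")
def small_results(small_cohort):
    genomes, truth = small_cohort
    return [analyze_genome(g) for g in genomes], truth
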