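import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_dataset():
    """One small ground-truthed simulation shared by cross-module tests:
    3 subgenomes x 2 chromosomes x 100 kb, 2 insertions, 20x depth."""
    from tdnawalk.simulator import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        seed=7,
        chromosomes_per_subgenome=2,
        chromosome_length=100_000,
        n_insertions=2,
        amplicon_depth=20,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_detection(small_dataset):
    from tdnawalk.pipeline import detect_insertions

    return detect_insertions(
        small_dataset.library.read_pairs,
        small_dataset.constructs,
        small_dataset.genome,
    )
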