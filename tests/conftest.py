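import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


@pytest.fixture
def small_sim_config():
    """A small but fully featured study configuration for pipeline tests."""
    from hypomre.simulate import SimConfig

    return SimConfig(
        seed=11,
        genome_length=60_000,
        n_accessions=3,
        n_pairs=4000,
    )
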