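import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nucpatterns as npx

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_batch(rng: np.random.Generator, n: int, length: int) -> npx.SequenceBatch:
    return npx.SequenceBatch(
        [(f"s{i}", random_dna(rng, length)) for i in range(n)],
        alignment="experimental_end",
    )


@pytest.fixture(scope="session")
def default_batch():
    """Default synthetic end-aligned batch (500 x 400 bp, AA/TT 10-bp signal)."""
    return npx.simulate_batch(npx.SimulationParams())


@pytest.fixture(scope="session")
def default_profiles(default_batch):
    batch, _ = default_batch
    return npx.profile_set(batch)
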