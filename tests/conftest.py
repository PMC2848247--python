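import numpy as np
import pytest

from dccmotif import SimulationConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def small_sim() -> SimulationConfig:
    """A scaled-down simulation for fast end-to-end tests."""
    return SimulationConfig(
        seed=7,
        target_length=120_000,
        background_length=120_000,
        planted_region_count=5,
        planted_region_length=3000,
        gene_count=20,
    )


def random_dna(rng: np.random.Generator, length: int, with_ambiguous=False) -> str:
    alphabet = "ACGTN" if with_ambiguous else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_ambiguous else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))
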