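import numpy as np
import pytest
from hypothesis import settings

from crossonc.genome import GenomeModel, ProbeSet, SampleProfile, StateThresholds

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_genome() -> GenomeModel:
    return GenomeModel(
        "toy",
        [("chr1", 10_000_000, 4_000_000), ("chr2", 8_000_000, 3_000_000)],
    )


@pytest.fixture
def toy_probes(toy_genome) -> ProbeSet:
    positions = {
        "chr1": np.arange(50_000, 10_000_000, 100_000),
        "chr2": np.arange(50_000, 8_000_000, 100_000),
    }
    ids = {c: [f"{c}_p{i}" for i in range(len(p))] for c, p in positions.items()}
    return ProbeSet(toy_genome, positions, ids)


@pytest.fixture
def thresholds() -> StateThresholds:
    return StateThresholds()


def make_profile(probes: ProbeSet, values, sample_id: str = "S1") -> SampleProfile:
    return SampleProfile(sample_id, np.asarray(values, dtype=float), probes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
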