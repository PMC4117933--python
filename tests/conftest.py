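import numpy as np
import pytest

from locuscn import PopulationSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-population cohort, tiny but rich enough for every stage."""
    cfg = SimConfig(
        populations=(
            PopulationSpec("POP1", 25, (0.1, 0.25, 0.45, 0.2)),
            PopulationSpec("POP2", 25, (0.05, 0.2, 0.5, 0.25)),
        ),
        region_length=50_000,
        window_size=1000,
        block_offset=(20_000, 30_000),
        gene_offset=(22_000, 28_000),
        coverage=(30, 30),
        mappability=0.9,
        seed=2024,
    )
    counts, truth = simulate_cohort(cfg)
    return cfg, counts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
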