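import numpy as np
import pytest

from neurocpm import SimulationConfig, generate_cohort

#: small site/group cells used by fast fixtures (n = 60)
SMALL_CELLS = {("GU", "TD"): 18, ("GU", "ASD"): 12, ("KK", "TD"): 20, ("KK", "ASD"): 10}


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A 20-node cohort small enough for brute-force oracles."""
    defaults = dict(
        n_per_site_group=dict(SMALL_CELLS),
        node_count=20,
        n_signal_edges=15,
        n_motion_edges=15,
        n_site_edges=15,
        beta_signal=0.12,  # stronger per-edge effect so n=60 has power
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_cohort():
    return generate_cohort(small_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
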