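import numpy as np
import pytest

from tmegraph.preprocessing import (
    BACKGROUND, ITIL, NECROSIS, STIL, STROMA, TUMOR, TTAImage,
)
from tmegraph.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture
def small_tta() -> TTAImage:
    """A hand-built 6x6 TTA-image with all compartments present."""
    g = np.full((6, 6), BACKGROUND, dtype=np.int8)
    g[1:4, 1:4] = TUMOR
    g[1, 1] = NECROSIS
    g[2, 2] = ITIL
    g[3, 3] = ITIL
    g[1:5, 4] = STROMA
    g[2, 4] = STIL
    g[4, 1:4] = STROMA
    g[4, 2] = STIL
    return TTAImage(grid=g, patient_id="toy")


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small effectful synthetic cohort shared across tests.

    Session-scoped because simulation plus graph work is the slowest part
    of the suite; tests must not mutate it.
    """
    cfg = SimConfig(seed=11, grid_rows=40, grid_cols=40,
                    tumor_seed_count=3, tumor_disc_radius=3.5)
    return simulate_cohort(24, cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
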