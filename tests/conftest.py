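import numpy as np
import pytest

from fcdiscrim.cohortsim import CohortConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Desk-scale cohort small enough for fast unit tests."""
    return CohortConfig(
        n_per_group={"NC": 6, "TPD": 5, "NTPD": 4},
        n_rois=32,
        n_modules=4,
        affected_nodes=tuple(range(4)),
        cerebellum_nodes=tuple(range(24, 32)),
        n_volumes=120,
        seed=11,
    )
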