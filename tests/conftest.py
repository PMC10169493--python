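import numpy as np
import pandas as pd
import pytest

from enterolink import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across tests (seed 0)."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced cohort config for fast end-to-end runs."""
    return dict(
        n_features={"rumen_metab": 60, "serum_metab": 40, "milk_metab": 30},
        n_blocks={"rumen_metab": 3, "serum_metab": 2, "milk_metab": 2},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def abundance_frame():
    return pd.DataFrame(
        [[0.2, 0.3, 0.5], [0.1, 0.6, 0.3], [0.4, 0.4, 0.2]],
        index=["s1", "s2", "s3"],
        columns=["g1", "g2", "g3"],
    )
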