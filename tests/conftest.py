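import numpy as np
import pandas as pd
import pytest

from sdohmpi.indicators import DeprivationMatrix
from sdohmpi.registry import default_registry
from sdohmpi.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def toy_matrix():
    """4 participants x 3 indicators: rows 110, 100, 111, 000."""
    return DeprivationMatrix(
        pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [1, 1, 1], [0, 0, 0]],
            columns=["i1", "i2", "i3"],
            index=pd.Index([0, 1, 2, 3], name="participant_id"),
        )
    )


@pytest.fixture(scope="session")
def small_cohort(registry):
    """One seeded synthetic cohort reused across read-only tests."""
    return generate_cohort(SimConfig(n_participants=400, seed=11), registry)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
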