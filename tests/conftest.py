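import numpy as np
import pandas as pd
import pytest

from pelagos.containers import OtuTable
from pelagos.synthetic import SimulationConfig, simulate_depth_transect_study


@pytest.fixture
def toy_table() -> OtuTable:
    """4 samples x 5 OTUs with hand-set counts."""
    counts = pd.DataFrame(
        [
            [10, 0, 3, 1, 0],
            [10, 5, 0, 1, 0],
            [10, 5, 3, 0, 0],
            [10, 5, 3, 1, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["o1", "o2", "o3", "o4", "o5"],
    )
    return OtuTable(counts)


@pytest.fixture(scope="session")
def small_study():
    """One small deterministic transect study shared across tests."""
    cfg = SimulationConfig(n_otus=80, n_reads_per_sample=1000, seed=1234)
    return simulate_depth_transect_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
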