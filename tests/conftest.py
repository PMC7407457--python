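import numpy as np
import pytest

import sparsegp as sp


@pytest.fixture(scope="session")
def small_dataset():
    """60 genotypes x 300 markers x 3 environments, cell values only."""
    cfg = sp.SimulationConfig(n_genotypes=60, n_markers=300, seed=42)
    return sp.simulate_dataset(cfg, with_plots=False)


@pytest.fixture(scope="session")
def small_blues(small_dataset):
    """Full-factorial adjusted-value table from the small dataset's cells."""
    return small_dataset.cell_values.rename(columns={"value": "blue"})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
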