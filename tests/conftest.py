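import numpy as np
import pandas as pd
import pytest

import hka


@pytest.fixture(scope="session")
def small_sim():
    """One-lineage, two-stage simulated experiment used across modules."""
    cfg = hka.SimulationConfig(n_genes=300, lineages=("L1",),
                               library_size_mean=1e6, seed=42)
    return hka.simulate_experiment(cfg)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 500, size=(40, 6))
    return hka.CountMatrix(pd.DataFrame(
        counts, index=[f"g{i}" for i in range(40)],
        columns=[f"s{j}" for j in range(6)]))
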