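import numpy as np
import pandas as pd
import pytest

import fragdex as fx


@pytest.fixture(scope="session")
def small_config():
    return fx.SimulationConfig(n_genes=80, n_hk_genes=10, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    design = fx.generate_design(small_config)
    counts, truth = fx.generate_counts(design, small_config)
    return design, counts, truth


@pytest.fixture(scope="session")
def small_tmm(small_dataset):
    _, counts, _ = small_dataset
    tmm, factors = fx.tmm_normalize(counts)
    return tmm, factors


@pytest.fixture
def toy_design():
    """5 treatment groups in duplicate."""
    treatments = np.repeat(["control", "AZM6", "AZM24", "CPF6", "CPF24"], 2)
    idx = [f"{t}_r{i % 2 + 1}" for i, t in enumerate(treatments)]
    return pd.DataFrame({"treatment": treatments, "replicate": [1, 2] * 5},
                        index=pd.Index(idx, name="sample_id"))
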