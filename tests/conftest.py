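import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rxpanel as rx

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset() -> rx.SyntheticDataset:
    """One-tissue dataset with strong DE signal and two modules."""
    cfg = rx.SimulationConfig(
        n_genes=400,
        n_de=20,
        log2_fc=2.0,
        dispersion=0.1,
        n_tissues=1,
        n_modules=2,
        module_size=15,
        module_rho=0.8,
        seed=42,
    )
    return rx.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    return rx.normalize(small_dataset.counts["adrenal"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_counts(values: np.ndarray, tissue: str = "t") -> rx.CountMatrix:
    g = [f"g{i}" for i in range(values.shape[0])]
    s = [f"s{j}" for j in range(values.shape[1])]
    return rx.CountMatrix(pd.DataFrame(values, index=g, columns=s), tissue)
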