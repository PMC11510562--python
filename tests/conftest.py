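import numpy as np
import pytest

import solmap as sm


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic molecule/logS table with ground truth (n=120, seed 7)."""
    spec = sm.SyntheticSolubilitySpec(n_molecules=120, noise_sd=0.3, seed=7)
    return sm.generate_solubility_dataset(spec)


@pytest.fixture(scope="session")
def fitted_results(small_dataset):
    """Bayesian ridge fit on the small synthetic table."""
    table, _ = small_dataset
    return sm.BayesianRidge.from_dataframe(table).fit()


@pytest.fixture(scope="session")
def random_molecules():
    """100 held-out molecules from the same generative family."""
    spec = sm.SyntheticSolubilitySpec(n_molecules=100, noise_sd=0.0, seed=123)
    table, _ = sm.generate_solubility_dataset(spec)
    return list(table.smiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
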