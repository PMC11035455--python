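import numpy as np
import pytest

from molppo import chem_data, synthetic_data


@pytest.fixture(scope="session")
def small_dataset():
    """Deduplicated 80-molecule synthetic dataset with mild noise."""
    table, oracle = synthetic_data.simulate_table(
        80, seed=11, oracle=synthetic_data.OracleSpec(noise_sd=0.2))
    rows = [(s, chem_data.ic50_to_pic50(v))
            for s, v in zip(table["smiles"], table["ic50_nM"])]
    dataset = chem_data.prepare_dataset(rows, seed=11)
    return dataset, oracle


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free oracle labels: the regression target is exactly learnable."""
    table, oracle = synthetic_data.simulate_table(
        150, seed=7, oracle=synthetic_data.OracleSpec(noise_sd=0.0),
        duplicate_rate=0.0)
    rows = [(s, chem_data.ic50_to_pic50(v))
            for s, v in zip(table["smiles"], table["ic50_nM"])]
    dataset = chem_data.prepare_dataset(rows, seed=7)
    return dataset, oracle


@pytest.fixture
def rng():
    return np.random.default_rng(0)
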