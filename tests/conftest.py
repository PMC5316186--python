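import numpy as np
import pandas as pd
import pytest

from stagedyn import preprocess
from stagedyn.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Mid-size synthetic dataset with all planted gene classes."""
    config = SimulationConfig(n_genes=800, rng_seed=42)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def null_dataset():
    """Dataset with no planted structure at all."""
    config = SimulationConfig(
        n_genes=600,
        rng_seed=43,
        frac_constant_deg=0.0,
        frac_progressive_deg=0.0,
        frac_transition=0.0,
        n_modules=0,
        n_stage_modules=0,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def planted_sheet(planted_dataset):
    return preprocess.add_stage_labels(planted_dataset.sample_sheet)


@pytest.fixture(scope="session")
def planted_normalized(planted_dataset):
    counts = preprocess.filter_low_expression(planted_dataset.counts)
    sf = preprocess.estimate_size_factors(counts)
    return preprocess.normalize(counts, sf)
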