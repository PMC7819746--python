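import numpy as np
import pandas as pd
import pytest

from mirenrich import preprocessing, synthetic_data
from mirenrich.io_formats import CountMatrix, SampleSheet


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down simulation for fast unit tests (structure preserved)."""
    return synthetic_data.SimulationSpec(
        n_mirna=200, replicates=4, enriched_fraction=0.08,
        enrichment_fold=8.0, dynamic_fraction=0.0,
        libsize_mu=2e5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    counts, sheet, truth = synthetic_data.simulate_cell_counts(small_spec)
    return counts, sheet, truth


@pytest.fixture(scope="session")
def small_logcpm(small_dataset):
    counts, sheet, _ = small_dataset
    factors = preprocessing.tmm_factors(counts)
    return preprocessing.cpm(counts, norm_factors=factors, log=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_counts():
    """3 miRNAs x 4 samples, two conditions, one cell type."""
    cm = CountMatrix(["miR-a", "miR-b", "miR-c"],
                     ["s1", "s2", "s3", "s4"],
                     np.array([[10, 12, 11, 9],
                               [100, 90, 110, 95],
                               [5, 6, 4, 7]]))
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "cell_type": ["PT"] * 4,
        "condition": ["sham", "sham", "UUO7", "UUO7"],
        "replicate": [1, 2, 1, 2]}))
    return cm, sheet
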