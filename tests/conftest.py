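import numpy as np
import pandas as pd
import pytest

import dispbias as db


@pytest.fixture(scope="session")
def small_dataset():
    """2000-gene NB dataset (alpha=0.1, 5+5, 30% DE) shared across tests."""
    cfg = db.SimConfig(
        n_genes=2000, n_samples_per_group=(5, 5), dispersion=0.1, seed=11
    )
    cm, truth = db.simulate_dataset(cfg)
    return cm, truth


@pytest.fixture()
def tiny_counts():
    """Hand-sized count matrix with two groups of three samples."""
    counts = pd.DataFrame(
        {
            "a1": [10, 100, 5, 0],
            "a2": [12, 90, 5, 0],
            "a3": [11, 110, 5, 0],
            "b1": [20, 100, 5, 0],
            "b2": [22, 95, 5, 0],
            "b3": [18, 105, 5, 0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    group = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    return counts, group
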