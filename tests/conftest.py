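import numpy as np
import pandas as pd
import pytest

import emtraj as et


@pytest.fixture(scope="session")
def small_cfg():
    """A compact cohort: big enough for projection, fast for every test."""
    return et.SimulationConfig(
        n_cells=150, n_bulk=80, n_genes=60, noise_sd=0.3,
        batch_shift=0.5, purity_range=(0.6, 1.0), n_tissues=3, seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    ref, truth = et.simulate_reference(small_cfg)
    return ref, truth


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_reference):
    ref, _ = small_reference
    bulk, truth = et.simulate_bulk_cohort(small_cfg, ref)
    return bulk, truth


@pytest.fixture()
def tiny_matrix():
    return et.ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0]]),
        pd.Index(["GA", "GB"]),
        pd.Index(["S1", "S2"]),
    )
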