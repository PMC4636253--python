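import numpy as np
import pytest

from matchsym import (
    SimulationParams,
    gpa,
    make_anchor_template,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def template():
    return make_anchor_template()


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 8-individual dataset with the default variance ladder."""
    return simulate_dataset(SimulationParams(n_individuals=8, seed=42))


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    return gpa(small_dataset.records, reflect_side="left")


@pytest.fixture(scope="session")
def study_aligned():
    """25-individual dataset matching the reference design (R=2, 40 points)."""
    ds = simulate_dataset(SimulationParams(n_individuals=25, seed=7))
    return gpa(ds.records, reflect_side="left")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
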