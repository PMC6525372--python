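import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import splitgsea as sg

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalogue():
    return sg.gene_set_catalogue()


@pytest.fixture(scope="session")
def collection(catalogue):
    return catalogue.collection()


@pytest.fixture(scope="session")
def small_dataset():
    """One fixed 50-sample synthetic benchmark realization."""
    return sg.simulate_dataset(25, random_state=11)


def random_small_dataset(rng, n_genes=None, n_per_class=None):
    """Tiny random continuous dataset for property tests."""
    n_genes = n_genes or int(rng.integers(3, 21))
    n_per_class = n_per_class or int(rng.integers(2, 7))
    values = rng.normal(size=(n_genes, 2 * n_per_class))
    return sg.ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        values=values,
        sample_ids=[f"s{i}" for i in range(2 * n_per_class)],
        phenotype=np.array(["X"] * n_per_class + ["Y"] * n_per_class),
        classes=("X", "Y"),
    )
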