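import numpy as np
import pytest

from phenoclust.prep import prepare_task_matrix
from phenoclust.simdata import CohortSpec, generate_cohort, inject_missingness


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-like synthetic cohort: 45 SZ / 47 HC, planted 3-cluster structure."""
    spec = CohortSpec(seed=7)
    return inject_missingness(generate_cohort(spec), spec), spec


@pytest.fixture(scope="session")
def prepared_default(default_cohort):
    table, _ = default_cohort
    return prepare_task_matrix(table)


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated spherical Gaussian clusters in 10 dimensions."""
    rng = np.random.default_rng(42)
    centers = np.zeros((3, 10))
    centers[0, :5] = -2.5
    centers[1, :5] = 2.5
    centers[2, 5:] = 3.0
    X = np.vstack([c + rng.normal(0, 1, (30, 10)) for c in centers])
    labels = np.repeat([0, 1, 2], 30)
    return X, labels
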