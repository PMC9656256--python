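import numpy as np
import pytest

from fconn.cohort import CohortSpec, generate_cohort
from fconn.connectivity import pearson_connectivity


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort at the study conditions (166 regions,
    192 timepoints, 49 controls vs 41 patients, default planted effects)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_connectivity(default_cohort):
    return [pearson_connectivity(s.timeseries) for s in default_cohort.subjects]


def random_weight_matrix(rng, n, nonnegative=True):
    """Random symmetric weight matrix with zero diagonal."""
    a = rng.random((n, n)) if nonnegative else rng.normal(size=(n, n))
    w = (a + a.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w
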