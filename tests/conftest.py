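import numpy as np
import pandas as pd
import pytest

from trinetomics import CohortConfig, OmicsMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with strong planted structure, shared across tests."""
    cfg = CohortConfig(n_samples=150, n_mgs=30, n_metabolites=60, n_biomarkers=12,
                       n_factors=5, loading=0.8, module_size_range=(5, 12), seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def toy_matrix():
    data = pd.DataFrame(
        [[0.2, 0.3, 0.5], [0.1, 0.4, 0.5], [0.6, 0.1, 0.3], [0.25, 0.25, 0.5]],
        index=["s1", "s2", "s3", "s4"], columns=["f1", "f2", "f3"])
    return OmicsMatrix(data, "microbiome_mgs")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
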