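import numpy as np
import pandas as pd
import pytest

from ptcnmf.readwrite import ExpressionMatrix
from ptcnmf.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort with planted rank-3 structure (300 x 120)."""
    cfg = SyntheticConfig(n_genes=300, n_samples=120, noise_sd=0.2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-free expression and tight archetypes: four well-separated
    activity clusters for exact-recovery checks."""
    cfg = SyntheticConfig(n_genes=200, n_samples=60, noise_sd=0.0,
                          activity_dispersion=0.05, seed=5)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                        index=["G1", "G2"], columns=["S1", "S2"])
    return ExpressionMatrix(data)
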