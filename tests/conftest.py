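import numpy as np
import pandas as pd
import pytest

import underdx as u


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """5,000 patients with an elevated prevalence so the exposure has support."""
    params = u.CohortParams(n_patients=5_000, theta_true=0.05,
                            sensitivity_true=0.7, seed=42)
    return u.generate_cohort(params)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Default-parameter cohort at a reduced size for fast structural checks."""
    return u.generate_cohort(u.CohortParams(n_patients=20_000, seed=3))


@pytest.fixture
def tiny_cohort() -> pd.DataFrame:
    """Three unreported patients; small enough to enumerate the latent space."""
    return pd.DataFrame({
        "admission": [1, 0, 1],
        "reported_smi": ["none", "mdd", "none"],
        "age_years": [40.0, 60.0, 25.0],
        "female": [1, 0, 0],
        "race": ["white", "black", "other"],
        "hispanic": [0, 0, 1],
        "selim": [2, 0, 5],
    })


@pytest.fixture
def tiny_truth() -> u.ModelParams:
    return u.ModelParams(
        beta0=-1.0, beta1=1.2,
        beta=np.array([0.3, 0.2, 0.25, 0.03, 0.27, 0.07, -0.19, 0.09, 0.30]),
        theta=0.3, s=0.5)
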