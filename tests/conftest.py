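import numpy as np
import pytest

from recurroc import DGPSpec, RiskDefinition, fit_em, simulate_dataset

RISK = RiskDefinition(r=2, t=5.0)


@pytest.fixture(scope="session")
def risk():
    return RISK


@pytest.fixture(scope="session")
def gamma_dataset():
    """Moderate gamma-frailty dataset with an informative marker."""
    return simulate_dataset(DGPSpec(n=300, beta1=0.5, theta=0.5, seed=11))


@pytest.fixture(scope="session")
def gamma_fit(gamma_dataset):
    return fit_em(gamma_dataset.observed)


@pytest.fixture(scope="session")
def small_datasets():
    """Five seeded datasets spanning frailty and censoring settings."""
    specs = [
        DGPSpec(n=120, beta1=0.5, theta=0.5, seed=1),
        DGPSpec(n=120, beta1=0.0, theta=1.0, seed=2),
        DGPSpec(n=120, beta1=0.5, theta=0.0, seed=3),
        DGPSpec(n=120, beta1=0.5, theta=0.5, censoring="independent_uniform", seed=4),
        DGPSpec(n=120, beta1=-0.3, theta=0.5, censoring="covariate_dependent", seed=5),
    ]
    return [simulate_dataset(s) for s in specs]
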