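import numpy as np
import pandas as pd
import pytest

from ritisurv.cure_model import (
    CureModelFit,
    IncidenceParams,
    LatencyParams,
    fit_mixture_cure,
)
from ritisurv.simulation import SimulationConfig, assemble_dataset


def make_fit(gamma0, gamma, lambda_e, nu_e, beta_e) -> CureModelFit:
    """Hand-built cure-model 'fit' for testing downstream components."""
    inc = IncidenceParams(gamma0, np.atleast_1d(gamma))
    lat = LatencyParams(lambda_e, nu_e, np.atleast_1d(beta_e))
    return CureModelFit(
        incidence=inc,
        latency=lat,
        posterior_weights=np.empty(0),
        loglik_trace=np.array([0.0]),
        converged=True,
        n_iter=0,
    )


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Moderate simulated cohort (scenario ii, r=0.5) shared across tests."""
    cfg = SimulationConfig(scenario="ii", r=0.5, beta_z=1.0, nu=1.0, N=600, seed=42)
    return assemble_dataset(cfg)


@pytest.fixture(scope="session")
def small_cohort_fit(small_cohort) -> CureModelFit:
    return fit_mixture_cure(small_cohort)
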