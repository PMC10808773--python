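import numpy as np
import pytest

from pinebird import MCMCConfig, StudyDesign, TrueParameters, fit_activity_glmm, fit_occupancy
from pinebird.glmm import GLMMData
from pinebird.occupancy import OccupancyModelData
from pinebird.synth import simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One moderate synthetic bundle shared across tests (3 visits/site-season)."""
    return simulate_dataset(
        StudyDesign(visits_per_site_season=(3, 3), seed=7), TrueParameters(), seed=7
    )


@pytest.fixture(scope="session")
def occ_fit(dataset):
    """Short occupancy fit for structural/diagnostic tests (not recovery)."""
    data = OccupancyModelData.from_frames(dataset.sites, dataset.covariates, dataset.surveys)
    return fit_occupancy(
        data, config=MCMCConfig(n_chains=2, n_iter=1600, burn_in=600, thin=2, seed=3)
    )


@pytest.fixture(scope="session")
def glmm_fit(dataset):
    """Short activity-GLMM fit for structural/diagnostic tests."""
    data = GLMMData.from_frames(dataset.vocals, dataset.covariates, dataset.sites)
    return fit_activity_glmm(
        data, config=MCMCConfig(n_chains=2, n_iter=1600, burn_in=600, thin=2, seed=3)
    )
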