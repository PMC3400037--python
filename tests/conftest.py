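import numpy as np
import pytest

from sohga.data_io import DoseRecord, ObservationRecord, PKDataset
from sohga.estimation import EstimationSettings
from sohga.model_spec import ModelSpec
from sohga.simdata import CovariateSimConfig, TrueModelConfig, simulate_covariates, simulate_dataset


def make_dataset(subjects, doses, observations, covariates=None, kinds=None):
    """Hand-build a validated PKDataset from plain tuples."""
    ds = PKDataset(
        subjects=list(subjects),
        doses=[DoseRecord(*d) for d in doses],
        observations=[ObservationRecord(*o) for o in observations],
        covariates=covariates or {s: {} for s in subjects},
        covariate_kinds=kinds or {},
    )
    return ds.validate()


def iv_dataset(cl, v, dose, times, n_subj=1, dv_fn=None):
    """Noise-free one-compartment bolus data for quick estimator checks."""
    subjects = [str(i + 1) for i in range(n_subj)]
    doses = [(s, 0.0, dose) for s in subjects]
    obs = []
    for s in subjects:
        for t in times:
            c = dose / v * np.exp(-cl / v * t)
            obs.append((s, float(t), float(dv_fn(c) if dv_fn else c)))
    return make_dataset(subjects, doses, obs)


@pytest.fixture(scope="session")
def covariates_200():
    return simulate_covariates(CovariateSimConfig(n_subjects=200, seed=20120706))


@pytest.fixture(scope="session")
def sim_dataset_200(covariates_200):
    ds, truth = simulate_dataset(covariates_200, TrueModelConfig(),
                                 seed=20120707, with_truth=True)
    return ds, truth


@pytest.fixture(scope="session")
def fast_settings():
    return EstimationSettings(run_covariance=False)


def linear_test_spec(theta=2.0, omega=0.5, sigma2=0.25) -> ModelSpec:
    """Constant-prediction model with additive eta: marginal N(theta, w^2+s^2)."""
    return ModelSpec(
        structural_kind="linear_test",
        iiv={"CL": "additive"},
        residual="additive",
        initial={"CL": theta, "omega_CL": omega, "sigma_add": sigma2},
    ).fill_defaults()


def one_obs_dataset(values):
    """One observation per subject at t=0.25 after a unit dose."""
    subjects = [str(i + 1) for i in range(len(values))]
    doses = [(s, 0.0, 1.0) for s in subjects]
    obs = [(s, 0.25, float(v)) for s, v in zip(subjects, values)]
    return make_dataset(subjects, doses, obs)
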