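import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize_scalar

from sohga.data_io import DoseRecord
from sohga.estimation import (
    EstimationSettings, covariance_step, empirical_bayes_etas, fit_model, neg2ll,
)
from sohga.estimation import _fd_hessian
from sohga.model_spec import ModelSpec, ParameterVector
from sohga.structural import concentration, StructuralParams

from conftest import iv_dataset, linear_test_spec, make_dataset, one_obs_dataset


LOG_2PI = np.log(2 * np.pi)


def pv(thetas, omegas=None, sigmas=None):
    return ParameterVector(thetas=thetas, omegas=omegas or {}, sigmas=sigmas or {})


class TestClosedFormGaussian:
    """linear_test with additive eta: exact marginal N(theta, w^2 + s^2)."""

    def analytic_neg2ll(self, y, theta, omega, sigma2):
        var = omega ** 2 + sigma2
        return float(np.sum(np.log(var) + (y - theta) ** 2 / var))

    @pytest.mark.parametrize("method", ["FO", "FOCE_I"])
    def test_matches_closed_form(self, method):
        rng = np.random.default_rng(7)
        y = rng.normal(2.0, 0.8, size=12)
        ds = one_obs_dataset(y)
        spec = linear_test_spec(theta=2.0, omega=0.5, sigma2=0.25)
        params = pv({"CL": 2.0}, {"omega_CL": 0.5}, {"sigma_add": 0.25})
        got = neg2ll(spec, params, ds, EstimationSettings(method=method))
        assert got == pytest.approx(self.analytic_neg2ll(y, 2.0, 0.5, 0.25), abs=1e-8)

    def test_include_2pi_adds_constant(self):
        y = [1.9, 2.2, 2.4]
        ds = one_obs_dataset(y)
        spec = linear_test_spec()
        params = pv({"CL": 2.0}, {"omega_CL": 0.5}, {"sigma_add": 0.25})
        a = neg2ll(spec, params, ds, EstimationSettings(include_2pi=False))
        b = neg2ll(spec, params, ds, EstimationSettings(include_2pi=True))
        assert b - a == pytest.approx(3 * LOG_2PI, abs=1e-10)


class TestNoIIV:
    def test_perfect_fit_with_unit_sigma_gives_zero_obv(self):
        ds = iv_dataset(cl=1.0, v=5.0, dose=10.0, times=[0.5, 1, 2, 4], n_subj=3)
        spec = ModelSpec("onecpt_iv", residual="additive",
                         initial={"CL": 1.0, "V": 5.0, "sigma_add": 1.0}).fill_defaults()
        params = pv({"CL": 1.0, "V": 5.0}, sigmas={"sigma_add": 1.0})
        for method in ("FO", "FOCE_I"):
            assert neg2ll(spec, params, ds,
                          EstimationSettings(method=method)) == pytest.approx(0.0, abs=1e-9)

    def test_fo_equals_focei_without_iiv(self):
        rng = np.random.default_rng(3)
        ds = iv_dataset(cl=1.3, v=4.0, dose=10.0, times=[0.5, 1, 2, 4, 8],
                        n_subj=6, dv_fn=lambda c: c * (1 + 0.1 * rng.standard_normal()))
        spec = ModelSpec("onecpt_iv", residual="proportional",
                         initial={"CL": 1.0, "V": 5.0, "sigma_prop": 0.02}).fill_defaults()
        params = pv({"CL": 1.2, "V": 4.4}, sigmas={"sigma_prop": 0.02})
        a = neg2ll(spec, params, ds, EstimationSettings(method="FO"))
        b = neg2ll(spec, params, ds, EstimationSettings(method="FOCE_I"))
        assert a == b


def quadrature_neg2ll(ds, spec_params, omega, sigma_prop2, n_nodes=64):
    """Independent oracle: adaptive Gauss-Hermite integration of the exact
    marginal likelihood for a one-compartment bolus model with one
    exponential eta on CL and proportional error."""
    cl, v, dose = spec_params
    total = 0.0
    by_subj = {}
    for o in ds.observations:
        by_subj.setdefault(o.subject_id, []).append(o)
    nodes, weights = hermegauss(n_nodes)
    for sid, obs in by_subj.items():
        t = np.array([o.time for o in obs])
        y = np.array([o.dv for o in obs])

        def nll(eta):
            f = dose / v * np.exp(-cl * np.exp(eta) / v * t)
            r = np.maximum(f * f * sigma_prop2, 1e-300)
            return (0.5 * np.sum(np.log(2 * np.pi * r) + (y - f) ** 2 / r)
                    + 0.5 * eta ** 2 / omega ** 2 + 0.5 * np.log(2 * np.pi * omega ** 2))

        res = minimize_scalar(nll, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        mode = res.x
        h = (nll(mode + 1e-4) - 2 * nll(mode) + nll(mode - 1e-4)) / 1e-8
        scale = 1.0 / np.sqrt(max(h, 1e-6))
        z = mode + scale * nodes
        vals = np.array([-nll(zi) for zi in z])
        log_integrand = vals + 0.5 * nodes ** 2  # cancel the e^{-x^2/2} weight
        m = log_integrand.max()
        integral = np.exp(m) * np.sum(weights * np.exp(log_integrand - m)) * scale
        total += -2.0 * np.log(integral)
    n = sum(len(o) for o in by_subj.values())
    # the package's OBV convention drops the n*log(2*pi) constant
    return total - n * LOG_2PI


class TestAgainstQuadrature:
    def test_focei_obv_close_to_exact_marginal(self):
        rng = np.random.default_rng(11)
        cl, v, dose, omega, sp2 = 1.0, 5.0, 10.0, 0.3, 0.01
        subjects = [str(i) for i in range(8)]
        times = [0.5, 1, 2, 4, 8]
        doses = [(s, 0.0, dose) for s in subjects]
        obs = []
        for s in subjects:
            cli = cl * np.exp(rng.normal(0, omega))
            for t in times:
                c = dose / v * np.exp(-cli / v * t)
                obs.append((s, t, c * (1 + rng.normal(0, np.sqrt(sp2)))))
        ds = make_dataset(subjects, doses, obs)
        spec = ModelSpec("onecpt_iv", iiv={"CL": "exponential"},
                         residual="proportional",
                         initial={"CL": cl, "V": v, "omega_CL": omega,
                                  "sigma_prop": sp2}).fill_defaults()
        params = pv({"CL": cl, "V": v}, {"omega_CL": omega}, {"sigma_prop": sp2})
        got = neg2ll(spec, params, ds, EstimationSettings(method="FOCE_I"))
        oracle = quadrature_neg2ll(ds, (cl, v, dose), omega, sp2)
        assert got == pytest.approx(oracle, abs=0.5)


class TestFitModel:
    def test_recovers_parameters_from_clean_data(self):
        rng = np.random.default_rng(5)
        ds = iv_dataset(cl=0.763, v=1.94, dose=100.0,
                        times=[0.25, 0.5, 1, 2, 3, 6, 10, 24], n_subj=20,
                        dv_fn=lambda c: max(c * (1 + 0.02 * rng.standard_normal()), 1e-9))
        spec = ModelSpec("onecpt_iv", residual="proportional",
                         initial={"CL": 1.0, "V": 1.0, "sigma_prop": 0.04}).fill_defaults()
        res = fit_model(spec, ds)
        assert res.converged
        assert res.params.thetas["CL"] == pytest.approx(0.763, rel=0.02)
        assert res.params.thetas["V"] == pytest.approx(1.94, rel=0.02)

    def test_starting_at_optimum_does_not_worsen(self):
        rng = np.random.default_rng(6)
        ds = iv_dataset(cl=1.0, v=4.0, dose=10.0, times=[0.5, 1, 2, 4], n_subj=8,
                        dv_fn=lambda c: c * (1 + 0.05 * rng.standard_normal()))
        spec = ModelSpec("onecpt_iv", residual="proportional",
                         initial={"CL": 1.0, "V": 4.0, "sigma_prop": 0.0025}).fill_defaults()
        first = fit_model(spec, ds)
        spec2 = ModelSpec("onecpt_iv", residual="proportional",
                          initial=dict(first.params.as_dict())).fill_defaults()
        second = fit_model(spec2, ds)
        assert second.obv <= first.obv + 1e-6

    def test_timeout_returns_nonconverged(self):
        ds = iv_dataset(cl=1.0, v=4.0, dose=10.0, times=[1, 2], n_subj=2)
        spec = ModelSpec("onecpt_iv", residual="additive",
                         initial={"CL": 2.0, "V": 2.0, "sigma_add": 1.0}).fill_defaults()
        res = fit_model(spec, ds, EstimationSettings(timeout=1e-9))
        assert not res.converged and not res.covariance_success

    def test_obv_invariant_to_subject_relabelling(self, fast_settings):
        rng = np.random.default_rng(8)
        times = [0.5, 2, 6]
        subjects = ["1", "2", "3"]
        obs = [(s, t, float(10 / 4 * np.exp(-t / 4) * (1 + 0.1 * rng.standard_normal())))
               for s in subjects for t in times]
        ds1 = make_dataset(subjects, [(s, 0.0, 10.0) for s in subjects], obs)
        renames = {"1": "B77", "2": "A3", "3": "zz"}
        ds2 = make_dataset([renames[s] for s in subjects],
                           [(renames[s], 0.0, 10.0) for s in subjects],
                           [(renames[s], t, dv) for (s, t, dv) in obs])
        spec = ModelSpec("onecpt_iv", iiv={"CL": "exponential"}, residual="proportional",
                         initial={"CL": 1.0, "V": 4.0, "omega_CL": 0.2,
                                  "sigma_prop": 0.01}).fill_defaults()
        params = pv({"CL": 1.0, "V": 4.0}, {"omega_CL": 0.2}, {"sigma_prop": 0.01})
        assert neg2ll(spec, params, ds1) == pytest.approx(
            neg2ll(spec, params, ds2), abs=1e-10)


class TestEmpiricalBayes:
    def test_tiny_omega_shrinks_etas_to_zero(self):
        rng = np.random.default_rng(9)
        ds = iv_dataset(cl=1.0, v=4.0, dose=10.0, times=[0.5, 1, 2, 4], n_subj=5,
                        dv_fn=lambda c: c * (1 + 0.1 * rng.standard_normal()))
        spec = ModelSpec("onecpt_iv", iiv={"CL": "exponential"}, residual="proportional",
                         initial={"CL": 1.0, "V": 4.0, "omega_CL": 1e-6,
                                  "sigma_prop": 0.01}).fill_defaults()
        params = pv({"CL": 1.0, "V": 4.0}, {"omega_CL": 1e-6}, {"sigma_prop": 0.01})
        etas, ipred = empirical_bayes_etas(spec, params, ds)
        assert np.max(np.abs(etas)) < 1e-6
        pop = concentration(StructuralParams("onecpt_iv", CL=1.0, V=4.0),
                            [DoseRecord("1", 0.0, 10.0)], np.array([0.5, 1, 2, 4]))
        np.testing.assert_allclose(ipred[:4], pop, rtol=1e-4)

    def test_no_iiv_gives_empty_etas_and_population_ipred(self):
        ds = iv_dataset(cl=1.0, v=4.0, dose=10.0, times=[0.5, 2], n_subj=3)
        spec = ModelSpec("onecpt_iv", residual="additive",
                         initial={"CL": 1.0, "V": 4.0, "sigma_add": 0.01}).fill_defaults()
        params = pv({"CL": 1.0, "V": 4.0}, sigmas={"sigma_add": 0.01})
        etas, ipred = empirical_bayes_etas(spec, params, ds)
        assert etas.shape == (3, 0)
        assert ipred == pytest.approx([10 / 4 * np.exp(-0.5 / 4), 10 / 4 * np.exp(-2 / 4)] * 3)

    def test_mode_tracks_true_eta_with_shrinkage(self):
        omega, eta_true = 0.3, 0.45
        cl, v, dose = 1.0, 5.0, 10.0
        times = np.array([0.5, 1, 2, 4, 8])
        c = dose / v * np.exp(-cl * np.exp(eta_true) / v * times)
        ds = make_dataset(["1"], [("1", 0.0, dose)],
                          [("1", float(t), float(ci)) for t, ci in zip(times, c)])
        spec = ModelSpec("onecpt_iv", iiv={"CL": "exponential"}, residual="proportional",
                         initial={"CL": cl, "V": v, "omega_CL": omega,
                                  "sigma_prop": 0.0025}).fill_defaults()
        params = pv({"CL": cl, "V": v}, {"omega_CL": omega}, {"sigma_prop": 0.0025})
        etas, _ = empirical_bayes_etas(spec, params, ds)
        # posterior mode lies between 0 and the true eta (shrinkage), close to truth
        assert 0.0 < etas[0, 0] <= eta_true + 1e-9
        assert etas[0, 0] == pytest.approx(eta_true, abs=0.1)


class TestCovarianceStep:
    def test_fd_hessian_exact_on_quadratic(self):
        A = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])

        def f(x):
            return 0.5 * x @ A @ x

        for scheme in ("central", "forward"):
            H = _fd_hessian(f, np.array([0.3, -0.2, 1.0]), 1e-4, scheme)
            np.testing.assert_allclose(H, A, atol=1e-5)

    def test_gaussian_model_standard_errors(self):
        rng = np.random.default_rng(21)
        n = 200
        y = rng.normal(2.0, 0.5, n)
        ds = one_obs_dataset(y)
        spec = ModelSpec("linear_test", residual="additive",
                         initial={"CL": 2.0, "sigma_add": 0.25}).fill_defaults()
        res = fit_model(spec, ds)
        assert res.converged and res.covariance_success
        mu_hat = res.params.thetas["CL"]
        s2_hat = res.params.sigmas["sigma_add"]
        # resolution limited by the outer ftol; far below SE(mean) ~ 0.035
        assert mu_hat == pytest.approx(np.mean(y), abs=1e-3)
        # SE(mean) = sqrt(sigma^2/n); off-diagonal vanishes at the MLE
        assert res.se["CL"] == pytest.approx(np.sqrt(s2_hat / n), rel=1e-3)
        assert abs(res.correlation[0, 1]) < 0.01
        assert res.condition_number == pytest.approx(1.0, abs=0.05)

    def test_failed_hessian_reported(self):
        # an exactly flat direction: an additive effect of a covariate that is
        # constant across subjects multiplies theta by (x - median) = 0
        rng = np.random.default_rng(4)
        subjects = ["1", "2", "3", "4"]
        obs = [(s, t, float(10 / 4 * np.exp(-t / 4) * (1 + 0.05 * rng.standard_normal())))
               for s in subjects for t in (0.5, 2.0, 6.0)]
        ds = make_dataset(subjects, [(s, 0.0, 10.0) for s in subjects], obs,
                          covariates={s: {"Z": 1.0} for s in subjects},
                          kinds={"Z": "continuous"})
        from sohga.model_spec import CovariateEffect
        spec = ModelSpec("onecpt_iv", residual="proportional",
                         effects=(CovariateEffect("CL", "Z", "add", reference=1.0),),
                         initial={"CL": 1.0, "V": 4.0, "sigma_prop": 0.0025,
                                  "beta_CL_Z_add": 0.0}).fill_defaults()
        params = pv({"CL": 1.0, "V": 4.0, "beta_CL_Z_add": 0.0},
                    sigmas={"sigma_prop": 0.0025})
        res = covariance_step(spec, params, ds)
        assert res.covariance_success is False
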