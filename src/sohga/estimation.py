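"""Maximum marginal-likelihood estimation for nonlinear mixed-effects PK models.

Implements the two linearization-based marginal likelihood approximations
used throughout population PK:

FO
    linearize the subject model around η = 0; the subject marginal is
    Gaussian with mean F(0) and covariance G·Ω·Gᵀ + R(0), G = ∂F/∂η.
FOCE-I
    find each subject's conditional mode η̂ (an inner optimization),
    linearize around η̂ and evaluate the residual variance at η̂
    ("interaction"); the marginal covariance is G(η̂)·Ω·G(η̂)ᵀ + R(η̂)
    and the linearized residual is y − F(η̂) + G(η̂)·η̂.

The objective value (OBV) is −2·log L with the n·log 2π constant dropped
by default, mimicking the "fixed constant offset" convention of
estimation software in this field; absolute OBVs are therefore only
comparable within this package, which is all that model selection needs.

Estimation is performed on a transformed scale — log for positive
structural parameters, ω's and σ's, natural for (sign-free) covariate
coefficients — with L-BFGS-B.  Every numerical failure (overflow,
singular marginal covariance, timeout) is absorbed into a non-converged
:class:`FitResult` rather than an exception, because the surrounding
searches must treat crashed fits as penalized candidates, not errors.

The implementation is vectorized across subjects: the inner Newton
iteration updates all subjects' η simultaneously and per-subject
marginal covariances are factorized with batched linear algebra, grouped
by observation count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .data_io import PKDataset
from .model_spec import ModelSpec, ParameterVector
from .structural import _one_dose_conc, _one_dose_conc_grads

__all__ = [
    "EstimationSettings",
    "FitResult",
    "neg2ll",
    "fit_model",
    "empirical_bayes_etas",
    "covariance_step",
]

_LARGE = 1e10   # sentinel objective for failed (non-finite) evaluations
_SOFT_CAP = 1e7  # objective values beyond this are log-compressed: far larger
                 # than any real OBV, yet monotone so the line search keeps
                 # a descent signal instead of a flat plateau
_ETA_CLIP = 20.0  # |η| cap during the inner search; exp(±20) stays finite
_LOG_2PI = float(np.log(2.0 * np.pi))


class _FitTimeout(Exception):
    pass


@dataclass
class EstimationSettings:
    """Knobs of the estimator.

    ``outer_tol`` is the relative objective tolerance of the outer
    optimizer; ``inner_tol`` the absolute gradient tolerance of the
    per-subject η mode search; ``fd_step`` the relative finite-difference
    step of the covariance-step Hessian; ``timeout`` a wall-clock cap in
    seconds after which the fit returns non-converged.
    """

    method: str = "FOCE_I"
    outer_tol: float = 1e-8
    max_evals: int = 4000
    inner_tol: float = 1e-5
    inner_max_iter: int = 40
    fd_step: float = 1e-3
    grad_eps: float = 1e-5
    timeout: float = 3600.0
    include_2pi: bool = False
    run_covariance: bool = True
    hessian_scheme: str = "central"
    #: optimize the cheap FO objective first and start FOCE-I from its
    #: optimum — the standard two-stage trick; final estimates are FOCE-I
    fo_presolve: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("FO", "FOCE_I"):
            raise ValueError(f"unknown estimation method {self.method!r}")
        if self.outer_tol <= 0 or self.inner_tol <= 0 or self.timeout <= 0:
            raise ValueError("tolerances and timeout must be positive")


@dataclass
class FitResult:
    params: ParameterVector
    obv: float
    converged: bool
    covariance_success: bool = False
    se: dict[str, float] | None = None
    rse_pct: dict[str, float] | None = None
    correlation: np.ndarray | None = None
    condition_number: float | None = None
    etas: np.ndarray | None = None
    ipred: np.ndarray | None = None
    evals: int = 0

    @property
    def max_offdiag_correlation(self) -> float | None:
        if self.correlation is None or self.correlation.shape[0] < 2:
            return 0.0 if self.correlation is not None else None
        c = np.abs(self.correlation - np.eye(self.correlation.shape[0]))
        return float(c.max())


# --- dataset design (geometry shared by every spec) -----------------------

class _Design:
    def __init__(self, ds: PKDataset) -> None:
        ds.validate()
        self.subjects = list(ds.subjects)
        sidx = {s: i for i, s in enumerate(self.subjects)}
        obs = [o for o in ds.observations if not o.missing_flag]
        self.n_subj = len(self.subjects)
        self.n_obs = len(obs)
        self.y = np.array([o.dv for o in obs], dtype=float)
        self.obs_subj = np.array([sidx[o.subject_id] for o in obs], dtype=int)
        self.obs_time = np.array([o.time for o in obs], dtype=float)
        # (dose, observation) pairs with obs at/after the dose, for superposition
        po, pt, pa, pd_ = [], [], [], []
        for d in ds.doses:
            si = sidx[d.subject_id]
            for j in np.nonzero((self.obs_subj == si) & (self.obs_time >= d.time))[0]:
                po.append(j)
                pt.append(self.obs_time[j] - d.time)
                pa.append(d.amount)
                pd_.append(d.duration)
        self.pair_obs = np.array(po, dtype=int)
        self.pair_tau = np.array(pt, dtype=float)
        self.pair_amt = np.array(pa, dtype=float)
        self.pair_dur = np.array(pd_, dtype=float)
        self.pair_subj = self.obs_subj[self.pair_obs]
        # batch subjects by observation count for vectorized linear algebra
        counts = np.bincount(self.obs_subj, minlength=self.n_subj)
        if np.any(counts == 0):
            raise ValueError("every subject needs at least one non-missing observation")
        self.groups: list[tuple[np.ndarray, np.ndarray]] = []
        obs_order = np.argsort(self.obs_subj, kind="stable")
        starts = np.concatenate([[0], np.cumsum(counts)])
        for m in np.unique(counts):
            subj_ids = np.nonzero(counts == m)[0]
            rows = np.stack([obs_order[starts[s]:starts[s + 1]] for s in subj_ids])
            self.groups.append((subj_ids, rows))
        self.cov = {name: np.array([ds.covariates[s][name] for s in self.subjects])
                    for name in ds.covariate_kinds}

    def per_subject_sum(self, per_obs: np.ndarray) -> np.ndarray:
        return np.bincount(self.obs_subj, weights=per_obs, minlength=self.n_subj)


def _get_design(ds: PKDataset) -> _Design:
    d = getattr(ds, "_design", None)
    if d is None:
        d = _Design(ds)
        ds._design = d
    return d


# --- the objective ---------------------------------------------------------

class _Objective:
    """neg2ll as a function of the packed, transformed parameter vector."""

    def __init__(self, spec: ModelSpec, ds: PKDataset, settings: EstimationSettings):
        self.spec = spec = spec.fill_defaults()
        self.settings = settings
        self.design = _get_design(ds)
        self.kind = spec.structural_kind
        self.names = list(spec.parameter_names)
        self.eta_params = spec.eta_params
        self.q = len(self.eta_params)
        self.iiv_kinds = [spec.iiv[p] for p in self.eta_params]
        cov_names = set(spec.covariate_theta_names)
        self.transforms = ["lin" if n in cov_names else "log" for n in self.names]
        self.x0 = self.pack([spec.initial[n] for n in self.names])
        lo = self.pack([spec.bounds[n][0] for n in self.names])
        hi = self.pack([spec.bounds[n][1] for n in self.names])
        self.bounds_t = list(zip(lo, hi))
        self.eta_warm = np.zeros((self.design.n_subj, self.q))
        self._analytic_grads = (self.kind in ("onecpt_iv", "linear_test")
                                and not np.any(self.design.pair_dur > 0))
        # exact second derivatives need the closed-form kernel AND log-scale
        # (exponential) random effects; linear_test's additive η is handled
        # explicitly inside _state
        self._analytic_hess = self._analytic_grads and (
            self.kind == "linear_test"
            or all(k == "exponential" for k in spec.iiv.values()))
        self.evals = 0
        self.deadline: float | None = None
        self._n_sigma = len(spec.sigma_names)
        self._n_omega = self.q
        self._n_cov = len(spec.covariate_theta_names)
        self._n_struct = len(spec.structural_names)

    # packing: natural -> transformed and back
    def pack(self, natural) -> np.ndarray:
        out = np.asarray(natural, dtype=float).copy()
        for i, tr in enumerate(self.transforms):
            if tr == "log":
                out[i] = np.log(max(out[i], 1e-300))
        return out

    def unpack(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=float).copy()
        for i, tr in enumerate(self.transforms):
            if tr == "log":
                out[i] = np.exp(out[i])
        return out

    def split(self, natural: np.ndarray):
        ns, nc, no = self._n_struct, self._n_cov, self._n_omega
        struct = dict(zip(self.spec.structural_names, natural[:ns]))
        covt = dict(zip(self.spec.covariate_theta_names, natural[ns:ns + nc]))
        omega = np.asarray(natural[ns + nc:ns + nc + no], dtype=float)
        sigma = dict(zip(self.spec.sigma_names, natural[ns + nc + no:]))
        return struct, covt, omega, sigma

    def parameter_vector(self, x: np.ndarray) -> ParameterVector:
        struct, covt, omega, sigma = self.split(self.unpack(x))
        return ParameterVector(
            thetas={**struct, **covt},
            omegas=dict(zip(self.spec.omega_names, omega)),
            sigmas=sigma,
        )

    # typical values per subject (vectorized Table-4 chain)
    def subject_tvs(self, struct: dict, covt: dict) -> dict[str, np.ndarray] | None:
        n = self.design.n_subj
        tvs = {}
        for p in self.spec.structural_names:
            tv = np.full(n, struct[p])
            for e in self.spec.effects_on(p):
                th = [covt[name] for name in e.theta_names]
                tv = e.apply(tv, self.design.cov[e.covariate], th)
            if self.kind != "linear_test" and (p != "Q") and np.any(tv <= 0):
                return None  # invalid evaluation -> estimation failure upstream
            tvs[p] = np.asarray(tv, dtype=float)
        return tvs

    def _individual(self, tvs: dict[str, np.ndarray], eta: np.ndarray) -> dict[str, np.ndarray]:
        ind = dict(tvs)
        for k, p in enumerate(self.eta_params):
            if self.iiv_kinds[k] == "exponential":
                ind[p] = tvs[p] * np.exp(eta[:, k])
            else:
                ind[p] = tvs[p] + eta[:, k]
        return ind

    def predict(self, ind: dict[str, np.ndarray]) -> np.ndarray:
        d = self.design
        pair_params = {n: v[d.pair_subj] for n, v in ind.items()}
        c = _one_dose_conc(self.kind, pair_params, d.pair_tau, d.pair_amt, d.pair_dur)
        return np.bincount(d.pair_obs, weights=c, minlength=d.n_obs)

    def _residual_var(self, F: np.ndarray, sigma: dict) -> np.ndarray:
        res = self.spec.residual
        if res == "additive":
            R = np.full_like(F, sigma["sigma_add"])
        elif res == "proportional":
            R = F * F * sigma["sigma_prop"]
        else:
            R = F * F * sigma["sigma_prop"] + sigma["sigma_add"]
        return np.maximum(R, 1e-290)

    def _F_R(self, tvs, eta, sigma):
        F = self.predict(self._individual(tvs, eta))
        return F, self._residual_var(F, sigma)

    def _eta_jacobian(self, tvs, eta, sigma, h: float = 1e-4):
        """∂F/∂η — analytic via the chain rule where the dose kernel has
        closed-form parameter derivatives, central differences otherwise."""
        d = self.design
        J = np.empty((d.n_obs, self.q))
        if self._analytic_grads and self.q:
            ind = self._individual(tvs, eta)
            pair_params = {n: v[d.pair_subj] for n, v in ind.items()}
            res = _one_dose_conc_grads(self.kind, pair_params, d.pair_tau,
                                       d.pair_amt, d.pair_dur, self.eta_params)
            if res is not None:
                _, grads = res
                for k, pname in enumerate(self.eta_params):
                    g = grads[pname]
                    if self.iiv_kinds[k] == "exponential":
                        g = g * pair_params[pname]  # dP/dη = P
                    J[:, k] = np.bincount(d.pair_obs, weights=g, minlength=d.n_obs)
                return J
        for k in range(self.q):
            dk = np.zeros_like(eta)
            dk[:, k] = h
            Fp = self.predict(self._individual(tvs, eta + dk))
            Fm = self.predict(self._individual(tvs, eta - dk))
            J[:, k] = (Fp - Fm) / (2.0 * h)
        return J

    def _inner_objective(self, tvs, eta, sigma, w2_inv):
        F, R = self._F_R(tvs, eta, sigma)
        r = self.design.y - F
        l_obs = self.design.per_subject_sum(np.log(R) + r * r / R)
        return F, R, l_obs + np.sum(eta * eta * w2_inv, axis=1)

    def _state(self, tvs, eta, sigma):
        """One combined pass: F, R, J = ∂F/∂η and (hot path only) the
        second derivatives Fh[:, k, m] = ∂²F/∂η_k∂η_m at the observations.

        The hot path covers the bolus one-compartment and constant test
        kinds, whose log-derivatives are closed-form; other kinds fall
        back to finite differences for J and return ``Fh = None`` (the
        Newton iteration then uses Fisher weights only).
        """
        d = self.design
        q = self.q
        if self._analytic_hess and q:
            ind = self._individual(tvs, eta)
            pp = {n: v[d.pair_subj] for n, v in ind.items()}
            if self.kind == "linear_test":
                c = np.broadcast_to(np.asarray(pp["CL"], dtype=float),
                                    d.pair_tau.shape)
                glog = {"CL": np.ones_like(c)}
                hlog = {("CL", "CL"): np.zeros_like(c)}
                if self.iiv_kinds[0] == "additive":
                    # F = CL + eta: dF/deta = 1, second derivative 0
                    c_base = np.asarray(pp["CL"], dtype=float)
                    F = np.bincount(d.pair_obs, weights=np.broadcast_to(
                        c_base, d.pair_tau.shape), minlength=d.n_obs)
                    J = np.ones((d.n_obs, 1))
                    Fh = np.zeros((d.n_obs, 1, 1))
                    return F, self._residual_var(F, sigma), J, Fh
            else:
                CL = np.asarray(pp["CL"], dtype=float)
                V = np.asarray(pp["V"], dtype=float)
                ktau = CL / V * d.pair_tau
                c = d.pair_amt / V * np.exp(-ktau)
                glog = {"CL": -ktau, "V": ktau - 1.0}
                hlog = {("CL", "CL"): -ktau, ("CL", "V"): ktau,
                        ("V", "CL"): ktau, ("V", "V"): -ktau}
            F = np.bincount(d.pair_obs, weights=c, minlength=d.n_obs)
            J = np.empty((d.n_obs, q))
            Fh = np.empty((d.n_obs, q, q))
            for k, pk in enumerate(self.eta_params):
                J[:, k] = np.bincount(d.pair_obs, weights=c * glog[pk],
                                      minlength=d.n_obs)
                for m in range(k, q):
                    pm = self.eta_params[m]
                    w = c * (hlog[(pk, pm)] + glog[pk] * glog[pm])
                    Fh[:, k, m] = Fh[:, m, k] = np.bincount(
                        d.pair_obs, weights=w, minlength=d.n_obs)
            return F, self._residual_var(F, sigma), J, Fh
        F, R = self._F_R(tvs, eta, sigma)
        J = self._eta_jacobian(tvs, eta, sigma) if q else np.empty((d.n_obs, 0))
        return F, R, J, None

    def _solve_eta(self, tvs, omega, sigma):
        """Per-subject MAP η̂, all subjects at once.

        Newton with the exact per-subject Hessian where second
        derivatives are analytic, damped Fisher scoring otherwise; each
        subject backtracks independently.  Returns (η̂, (F, R, J) at η̂)
        or None on numerical failure.
        """
        d = self.design
        q = self.q
        w2 = np.maximum(omega, 1e-12) ** 2
        w2_inv = 1.0 / w2
        # start each subject from the better of (warm start, 0): warm starts
        # carry over from previous outer iterations but can be poisoned by a
        # bad trial point, and η = 0 is always a safe prior-mode fallback
        eta_w = np.clip(self.eta_warm, -_ETA_CLIP, _ETA_CLIP)
        zeros = np.zeros_like(eta_w)
        if np.any(eta_w):
            _, _, l_w = self._inner_objective(tvs, eta_w, sigma, w2_inv)
            _, _, l_0 = self._inner_objective(tvs, zeros, sigma, w2_inv)
            use_warm = np.isfinite(l_w) & (l_w < l_0)
            eta = np.where(use_warm[:, None], eta_w, zeros)
            l = np.where(use_warm, l_w, l_0)
        else:
            eta = zeros
            _, _, l = self._inner_objective(tvs, eta, sigma, w2_inv)
        if not np.all(np.isfinite(l)):
            return None
        prop_sig = self.spec.residual in ("proportional", "combined")
        sp = sigma.get("sigma_prop", 0.0)
        state = None
        state_eta = None
        for _ in range(self.settings.inner_max_iter):
            F, R, J, Fh = self._state(tvs, eta, sigma)
            state = (F, R, J)
            state_eta = eta
            r = d.y - F
            # residual-model derivatives wrt F: R' = 2σp²F, R'' = 2σp²
            if prop_sig:
                Rp = 2.0 * sp * F
                phi1 = Rp / R - 2.0 * r / R - r * r * Rp / (R * R)
                phi2 = (2.0 / R + 2.0 * sp * (1.0 / R - r * r / (R * R))
                        - Rp * Rp / (R * R) + 4.0 * r * Rp / (R * R)
                        + 2.0 * r * r * Rp * Rp / (R ** 3))
                fisher_w = 2.0 / R + Rp * Rp / (R * R)
            else:
                phi1 = -2.0 * r / R
                phi2 = fisher_w = 2.0 / R
            grad = np.empty((d.n_subj, q))
            for k in range(q):
                grad[:, k] = d.per_subject_sum(phi1 * J[:, k]) \
                    + 2.0 * eta[:, k] * w2_inv[k]
            if np.max(np.abs(grad)) < self.settings.inner_tol:
                break
            H = np.empty((d.n_subj, q, q))
            for k in range(q):
                for m in range(k, q):
                    Hkm = d.per_subject_sum(phi2 * J[:, k] * J[:, m])
                    if Fh is not None:
                        Hkm = Hkm + d.per_subject_sum(phi1 * Fh[:, k, m])
                    H[:, k, m] = H[:, m, k] = Hkm
                H[:, k, k] += 2.0 * w2_inv[k]
            if Fh is not None and q <= 2:
                # swap in the (always PD) Fisher Hessian where the exact
                # one loses positive definiteness far from the mode
                if q == 1:
                    bad = H[:, 0, 0] <= 0
                else:
                    bad = (H[:, 0, 0] <= 0) | (
                        H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2 <= 0)
                if np.any(bad):
                    Hf = np.empty_like(H)
                    for k in range(q):
                        for m in range(k, q):
                            Hf[:, k, m] = Hf[:, m, k] = d.per_subject_sum(
                                fisher_w * J[:, k] * J[:, m])
                        Hf[:, k, k] += 2.0 * w2_inv[k]
                    H = np.where(bad[:, None, None], Hf, H)
            try:
                step = -np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                return None
            # per-subject backtracking: halve steps only where the objective worsens
            alpha = np.ones(d.n_subj)
            best_eta, best_l = eta, l
            for _ls in range(8):
                trial = np.clip(eta + alpha[:, None] * step, -_ETA_CLIP, _ETA_CLIP)
                _, _, l_t = self._inner_objective(tvs, trial, sigma, w2_inv)
                better = np.isfinite(l_t) & (l_t < best_l)
                best_eta = np.where(better[:, None], trial, best_eta)
                best_l = np.where(better, l_t, best_l)
                alpha = np.where(better, alpha, alpha * 0.5)
                if np.all(better):
                    break
            if np.max(np.abs(best_eta - eta)) < 1e-12:
                break
            eta, l = best_eta, best_l
        self.eta_warm = eta
        if state_eta is not eta:  # loop ended right after an η update
            F, R, J, _ = self._state(tvs, eta, sigma)
            state = (F, R, J)
        if state is None or np.any(np.isnan(state[0])):
            return None
        return eta, state

    def _marginal_neg2ll(self, tvs, eta, omega, sigma, state=None):
        """−2 log L of the linearized marginal around ``eta`` (0 for FO)."""
        d = self.design
        if state is not None:
            F, R, J = state
        else:
            F, R = self._F_R(tvs, eta, sigma)
            J = None
        r = d.y - F
        if self.q == 0:
            contrib = d.per_subject_sum(np.log(R) + r * r / R)
            return float(np.sum(contrib))
        if J is None:
            J = self._eta_jacobian(tvs, eta, sigma)
        w2 = np.maximum(omega, 1e-300) ** 2
        eps = r + np.sum(J * eta[d.obs_subj], axis=1)
        total = 0.0
        for subj_ids, rows in d.groups:
            Jg = J[rows]                       # (g, m, q)
            Sg = np.einsum("smk,k,snk->smn", Jg, w2, Jg)
            m = rows.shape[1]
            Sg[:, np.arange(m), np.arange(m)] += R[rows]
            try:
                L = np.linalg.cholesky(Sg)
            except np.linalg.LinAlgError:
                return None
            e = eps[rows][..., None]
            z = np.linalg.solve(L, e)[..., 0]
            logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
            total += float(np.sum(logdet) + np.sum(z * z))
        return total

    def neg2ll(self, x: np.ndarray) -> float:
        self.evals += 1
        if self.deadline is not None and time.monotonic() > self.deadline:
            raise _FitTimeout
        with np.errstate(all="ignore"):
            return self._neg2ll_inner(x)

    def _neg2ll_inner(self, x: np.ndarray) -> float:
        # overflow/invalid warnings are routine at rejected trial points;
        # non-finite results are caught and absorbed below
        natural = self.unpack(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(natural)):
            return _LARGE
        struct, covt, omega, sigma = self.split(natural)
        tvs = self.subject_tvs(struct, covt)
        if tvs is None:
            return _LARGE
        try:
            if self.q == 0 or self.settings.method == "FO":
                eta = np.zeros((self.design.n_subj, self.q))
                state = None
            else:
                solved = self._solve_eta(tvs, omega, sigma)
                if solved is None:
                    return _LARGE
                eta, state = solved
            val = self._marginal_neg2ll(tvs, eta, omega, sigma, state)
        except (FloatingPointError, OverflowError):
            return _LARGE
        if val is None or not np.isfinite(val):
            return _LARGE
        if val > _SOFT_CAP:
            # astronomically large finite values overflow the line-search
            # interpolation; compress them while preserving monotonicity
            return _SOFT_CAP + np.log1p(val - _SOFT_CAP)
        if self.settings.include_2pi:
            val += self.design.n_obs * _LOG_2PI
        return val

    def ebe(self, x: np.ndarray):
        """Final empirical-Bayes pass: η̂ per subject and individual predictions."""
        with np.errstate(all="ignore"):
            return self._ebe_inner(x)

    def _ebe_inner(self, x: np.ndarray):
        struct, covt, omega, sigma = self.split(self.unpack(np.asarray(x, dtype=float)))
        tvs = self.subject_tvs(struct, covt)
        if tvs is None:
            return np.zeros((self.design.n_subj, self.q)), np.full(self.design.n_obs, np.nan)
        if self.q == 0:
            F = self.predict(self._individual(tvs, np.zeros((self.design.n_subj, 0))))
            return np.zeros((self.design.n_subj, 0)), F
        solved = self._solve_eta(tvs, omega, sigma)
        eta = solved[0] if solved is not None else np.zeros((self.design.n_subj, self.q))
        F = self.predict(self._individual(tvs, eta))
        return eta, F


# --- public operations -----------------------------------------------------

def neg2ll(spec: ModelSpec, params: ParameterVector, ds: PKDataset,
           settings: EstimationSettings | None = None) -> float:
    """Objective value at the given parameters (no optimization)."""
    settings = settings or EstimationSettings()
    obj = _Objective(spec, ds, settings)
    values = params.as_dict()
    x = obj.pack([values[n] for n in obj.names])
    return obj.neg2ll(x)


def fit_model(spec: ModelSpec, ds: PKDataset,
              settings: EstimationSettings | None = None) -> FitResult:
    """Fit ``spec`` to ``ds`` by minimizing the marginal −2 log L.

    Never raises for numerical failure: timeouts, overflow and singular
    covariances come back as ``converged=False`` so that a surrounding
    search can penalize the candidate.
    """
    settings = settings or EstimationSettings()
    obj = _Objective(spec, ds, settings)
    obj.deadline = time.monotonic() + settings.timeout
    failed = FitResult(params=obj.parameter_vector(obj.x0), obv=float("inf"),
                       converged=False, evals=0)
    opts = {"maxfun": settings.max_evals, "ftol": settings.outer_tol,
            "gtol": 1e-4, "eps": settings.grad_eps}
    x_start = obj.x0
    try:
        if (settings.fo_presolve and settings.method == "FOCE_I" and obj.q > 0):
            fo = _Objective(spec, ds, replace(settings, method="FO"))
            fo.deadline = obj.deadline
            pre = optimize.minimize(fo.neg2ll, x_start, method="L-BFGS-B",
                                    bounds=obj.bounds_t, options=opts)
            obj.evals += fo.evals
            if np.isfinite(pre.fun) and pre.fun < _SOFT_CAP:
                x_start = np.asarray(pre.x, dtype=float)
        res = optimize.minimize(
            obj.neg2ll, x_start, method="L-BFGS-B", bounds=obj.bounds_t,
            options=opts,
        )
    except _FitTimeout:
        failed.evals = obj.evals
        return failed
    x_hat = np.asarray(res.x, dtype=float)
    obv = float(res.fun)
    if not np.isfinite(obv) or obv >= _SOFT_CAP:
        failed.evals = obj.evals
        return failed
    lo = np.array([b[0] for b in obj.bounds_t])
    hi = np.array([b[1] for b in obj.bounds_t])
    pinned = bool(np.any(np.minimum(x_hat - lo, hi - x_hat) < 1e-6))
    converged = bool(res.success) and not pinned
    try:
        etas, ipred = obj.ebe(x_hat)
    except _FitTimeout:
        etas, ipred = None, None
        converged = False
    result = FitResult(
        params=obj.parameter_vector(x_hat), obv=obv, converged=converged,
        etas=etas, ipred=ipred, evals=obj.evals,
    )
    if converged and settings.run_covariance:
        try:
            _covariance_from_objective(obj, x_hat, result, settings)
        except _FitTimeout:
            result.covariance_success = False
    return result


def empirical_bayes_etas(spec: ModelSpec, params: ParameterVector, ds: PKDataset,
                         settings: EstimationSettings | None = None):
    """Per-subject MAP η̂ and the matching individual predictions (IPRED)."""
    settings = settings or EstimationSettings()
    obj = _Objective(spec, ds, settings)
    values = params.as_dict()
    x = obj.pack([values[n] for n in obj.names])
    return obj.ebe(x)


def _fd_hessian(f, x: np.ndarray, rel_step: float, scheme: str) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    if scheme == "forward":
        f0 = f(x)
        fi = np.array([f(x + h[i] * _e(n, i)) for i in range(n)])
        for i in range(n):
            H[i, i] = (f(x + 2 * h[i] * _e(n, i)) - 2 * fi[i] + f0) / h[i] ** 2
            for j in range(i + 1, n):
                fij = f(x + h[i] * _e(n, i) + h[j] * _e(n, j))
                H[i, j] = H[j, i] = (fij - fi[i] - fi[j] + f0) / (h[i] * h[j])
        return H
    f0 = f(x)
    for i in range(n):
        ei = _e(n, i)
        H[i, i] = (f(x + h[i] * ei) - 2 * f0 + f(x - h[i] * ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = _e(n, j)
            fpp = f(x + h[i] * ei + h[j] * ej)
            fpm = f(x + h[i] * ei - h[j] * ej)
            fmp = f(x - h[i] * ei + h[j] * ej)
            fmm = f(x - h[i] * ei - h[j] * ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _e(n: int, i: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def _covariance_from_objective(obj: _Objective, x_hat: np.ndarray,
                               result: FitResult, settings: EstimationSettings) -> None:
    """SEs, correlation and condition number from a finite-difference Hessian.

    The Hessian of neg2ll/2 is taken on the estimation (transformed)
    scale and the covariance mapped to the reporting scale by the delta
    method.  The condition number is the eigenvalue ratio of the
    correlation matrix — the same matrix whose off-diagonals feed the
    |r| > 0.95 diagnostic.
    """
    H = _fd_hessian(lambda z: 0.5 * obj.neg2ll(z), x_hat,
                    settings.fd_step, settings.hessian_scheme)
    if not np.all(np.isfinite(H)):
        result.covariance_success = False
        return
    H = 0.5 * (H + H.T)
    try:
        np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        result.covariance_success = False
        return
    cov_t = np.linalg.inv(H)
    natural = obj.unpack(x_hat)
    jac = np.where([t == "log" for t in obj.transforms], natural, 1.0)
    cov = cov_t * np.outer(jac, jac)
    d = np.diag(cov)
    if np.any(d <= 0):
        result.covariance_success = False
        return
    se = np.sqrt(d)
    corr = cov / np.outer(se, se)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    eig = np.linalg.eigvalsh(corr)
    result.covariance_success = True
    result.se = dict(zip(obj.names, se))
    result.rse_pct = {n: 100.0 * s / abs(v) if v != 0 else float("inf")
                      for (n, s), v in zip(result.se.items(), natural)}
    result.correlation = corr
    result.condition_number = float(eig[-1] / eig[0]) if eig[0] > 0 else float("inf")
    if eig[0] <= 0:
        result.covariance_success = False


def covariance_step(spec: ModelSpec, params: ParameterVector, ds: PKDataset,
                    settings: EstimationSettings | None = None) -> FitResult:
    """Run only the covariance step at the given (already fitted) parameters."""
    settings = settings or EstimationSettings()
    obj = _Objective(spec, ds, settings)
    values = params.as_dict()
    x = obj.pack([values[n] for n in obj.names])
    result = FitResult(params=params, obv=obj.neg2ll(x), converged=True)
    _covariance_from_objective(obj, x, result, settings)
    return result
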