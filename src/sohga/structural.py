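"""Closed-form concentration predictions for linear compartment models.

All kinds are linear in dose, so multiple doses superpose.  Supported
kinds (NONMEM ADVAN/TRANS equivalents in parentheses):

``onecpt_iv``
    one-compartment, IV bolus/infusion (ADVAN1/TRANS2): CL, V
``onecpt_oral``
    one-compartment, first-order absorption (ADVAN2/TRANS2): CL, V, KA
``twocpt_iv``
    two-compartment, IV bolus/infusion (ADVAN3/TRANS4): CL, V, Q, V2
``twocpt_oral``
    two-compartment, first-order absorption (ADVAN4/TRANS4): CL, V, KA, Q, V2
``linear_test``
    constant prediction equal to its single parameter; an estimator
    validation kind with a closed-form Gaussian marginal, excluded from
    search spaces by default.

Bioavailability is fixed at 1.  The oral form's removable singularity at
KA = CL/V is replaced by its analytic limit D·k·τ·e^(−kτ)/V when
|KA − k|/k < 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StructuralParams", "PARAM_NAMES", "concentration", "half_life", "biexp_rates"]

#: structural parameter names per model kind, in estimation order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "onecpt_iv": ("CL", "V"),
    "onecpt_oral": ("CL", "V", "KA"),
    "twocpt_iv": ("CL", "V", "Q", "V2"),
    "twocpt_oral": ("CL", "V", "KA", "Q", "V2"),
    "linear_test": ("CL",),
}

_KA_SINGULARITY_TOL = 1e-8


@dataclass(frozen=True)
class StructuralParams:
    kind: str
    CL: float
    V: float = 1.0
    KA: float = 0.0
    Q: float = 0.0
    V2: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PARAM_NAMES:
            raise ValueError(f"unknown structural kind {self.kind!r}")
        names = PARAM_NAMES[self.kind]
        if self.kind != "linear_test":
            for name in names:
                value = getattr(self, name)
                if name == "Q":
                    if value < 0:
                        raise ValueError("Q must be >= 0")
                elif value <= 0:
                    raise ValueError(f"{name} must be > 0 (got {value})")

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES[self.kind]}


def half_life(CL: float, V: float) -> float:
    """Elimination half-life ln(2)·V/CL in hours."""
    if CL <= 0 or V <= 0:
        raise ValueError("CL and V must be positive")
    return float(np.log(2.0) * V / CL)


def biexp_rates(CL, V, Q, V2):
    """Hybrid rate constants (alpha, beta) of the two-compartment model.

    alpha·beta = k10·k21 and alpha+beta = k10+k12+k21 with micro-constants
    k10 = CL/V, k12 = Q/V, k21 = Q/V2.  Arrays broadcast.
    """
    V = np.asarray(V, dtype=float)
    V2 = np.asarray(V2, dtype=float)
    if np.any(V <= 0) or np.any(V2 <= 0):
        raise ValueError("V and V2 must be positive")
    k10 = np.asarray(CL, dtype=float) / V
    k12 = np.asarray(Q, dtype=float) / V
    k21 = np.asarray(Q, dtype=float) / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    if alpha.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def _expm1_div(lam, tau):
    """(1 − exp(−lam·tau))/lam with the lam→0 limit tau; used for infusions."""
    lam = np.asarray(lam, dtype=float)
    tau = np.asarray(tau, dtype=float)
    out = np.where(lam > 0, -np.expm1(-lam * tau) / np.where(lam > 0, lam, 1.0), tau)
    return out


def _one_dose_conc(kind: str, p: dict[str, np.ndarray], tau, amt, dur):
    """Concentration contribution of a single dose, tau = t − t_dose >= 0.

    ``p`` maps parameter names to scalars or arrays broadcastable with
    ``tau``; vectorized over (dose, time) pairs.
    """
    tau = np.asarray(tau, dtype=float)
    amt = np.asarray(amt, dtype=float)
    dur = np.asarray(dur, dtype=float)
    if kind == "linear_test":
        return np.broadcast_to(np.asarray(p["CL"], dtype=float), tau.shape).copy()

    CL = np.asarray(p["CL"], dtype=float)
    V = np.asarray(p["V"], dtype=float)
    k = CL / V

    if kind == "onecpt_iv":
        if not np.any(dur > 0):
            return amt / V * np.exp(-k * tau)
        bolus = dur <= 0
        # bolus: (D/V)·e^{−kτ}; infusion: R0/CL·(1−e^{−k·min(τ,d)})·e^{−k·max(τ−d,0)}
        te = np.minimum(tau, np.where(bolus, 0.0, dur))
        rate = amt / np.where(bolus, 1.0, dur)
        c_inf = rate / V * _expm1_div(k, te) * np.exp(-k * np.maximum(tau - dur, 0.0))
        c_bol = amt / V * np.exp(-k * tau)
        return np.where(bolus, c_bol, c_inf)

    if kind == "onecpt_oral":
        KA = np.asarray(p["KA"], dtype=float)
        near = np.abs(KA - k) <= _KA_SINGULARITY_TOL * k
        KA_safe = np.where(near, 2.0 * k, KA)  # placeholder where the limit branch is used
        general = amt * KA_safe / (V * (KA_safe - k)) * (np.exp(-k * tau) - np.exp(-KA_safe * tau))
        limit = amt * k * tau * np.exp(-k * tau) / V
        return np.where(near, limit, general)

    if kind in ("twocpt_iv", "twocpt_oral"):
        Q = np.asarray(p["Q"], dtype=float)
        V2 = np.asarray(p["V2"], dtype=float)
        k21 = Q / V2
        alpha, beta = biexp_rates(CL, V, Q, V2)
        alpha = np.asarray(alpha)
        beta = np.asarray(beta)
        denom = np.where(alpha - beta == 0.0, 1.0, alpha - beta)
        A = (alpha - k21) / denom
        B = (k21 - beta) / denom
        if kind == "twocpt_iv":
            bolus = dur <= 0
            te = np.minimum(tau, np.where(bolus, 0.0, dur))
            rate = amt / np.where(bolus, 1.0, dur)
            tail = np.maximum(tau - dur, 0.0)
            c_inf = rate / V * (
                A * _expm1_div(alpha, te) * np.exp(-alpha * tail)
                + B * _expm1_div(beta, te) * np.exp(-beta * tail)
            )
            c_bol = amt / V * (A * np.exp(-alpha * tau) + B * np.exp(-beta * tau))
            return np.where(bolus, c_bol, c_inf)
        KA = np.asarray(p["KA"], dtype=float)
        # nudge KA off the removable singularities at alpha and beta
        KA = np.where(np.abs(KA - alpha) <= _KA_SINGULARITY_TOL * alpha,
                      alpha * (1.0 + 1e-6), KA)
        KA = np.where(np.abs(KA - beta) <= np.maximum(_KA_SINGULARITY_TOL * beta, 1e-300),
                      KA * (1.0 + 1e-6) + 1e-12, KA)
        ca = (k21 - alpha) / ((KA - alpha) * (beta - alpha))
        cb = (k21 - beta) / ((KA - beta) * np.where(alpha - beta == 0.0, 1.0, alpha - beta))
        ck = (k21 - KA) / ((alpha - KA) * (beta - KA))
        return amt * KA / V * (
            ca * np.exp(-alpha * tau) + cb * np.exp(-beta * tau) + ck * np.exp(-KA * tau)
        )

    raise ValueError(f"unknown structural kind {kind!r}")


def _one_dose_conc_grads(kind: str, p: dict[str, np.ndarray], tau, amt, dur,
                         wrt: tuple[str, ...]):
    """(c, {name: dc/dparam}) for kinds with cheap analytic derivatives.

    Returns None when no analytic form is available (infusions, oral and
    two-compartment kinds fall back to finite differences upstream).
    """
    tau = np.asarray(tau, dtype=float)
    dur = np.asarray(dur, dtype=float)
    if kind == "linear_test":
        c = np.broadcast_to(np.asarray(p["CL"], dtype=float), tau.shape).copy()
        return c, {"CL": np.ones_like(c)}
    if kind == "onecpt_iv" and not np.any(dur > 0):
        CL = np.asarray(p["CL"], dtype=float)
        V = np.asarray(p["V"], dtype=float)
        k = CL / V
        c = np.asarray(amt, dtype=float) / V * np.exp(-k * tau)
        grads = {}
        if "CL" in wrt:
            grads["CL"] = -c * tau / V
        if "V" in wrt:
            grads["V"] = c * (k * tau - 1.0) / V
        return c, grads
    return None


def concentration(p: StructuralParams, doses, t):
    """Predicted concentration at time(s) ``t`` by superposition over ``doses``.

    Returns 0 before the first dose.  ``t`` may be a scalar or array.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("negative evaluation time")
    if not doses:
        raise ValueError("doses must be non-empty")
    out = np.zeros_like(t_arr)
    pd_ = p.as_dict()
    for d in doses:
        active = t_arr >= d.time
        if np.any(active):
            tau = t_arr[active] - d.time
            out[active] += _one_dose_conc(p.kind, pd_, tau, d.amount, d.duration)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out
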