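"""Model-comparison statistics: AIC, BIC, MPE, RMSE, Cohen's kappa.

Conventions: AIC = OBV + 2k and BIC = OBV + k·ln(n) with k the number of
estimated parameters and n the number of (non-missing) observations;
since OBV is −2 log L plus a constant, these are the usual information
criteria up to the same constant, which cancels in comparisons.
MPE = mean(IPRED − DV) and RMSE = sqrt(mean((IPRED − DV)²)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["aic", "bic", "mpe", "rmse", "cohen_kappa",
           "median_pct_param_difference", "ModelSummary", "ComparisonReport",
           "compare_models"]


def aic(obv: float, k: int) -> float:
    if k < 0:
        raise ValueError("k must be >= 0")
    return obv + 2.0 * k


def bic(obv: float, k: int, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return obv + k * float(np.log(n))


def _paired(ipred, dv):
    ipred = np.asarray(ipred, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if ipred.shape != dv.shape or ipred.size == 0:
        raise ValueError("ipred and dv must be equal-length and non-empty")
    return ipred, dv


def mpe(ipred, dv) -> float:
    """Mean prediction error (bias), prediction minus observation."""
    ipred, dv = _paired(ipred, dv)
    return float(np.mean(ipred - dv))


def rmse(ipred, dv) -> float:
    """Root mean squared prediction error."""
    ipred, dv = _paired(ipred, dv)
    return float(np.sqrt(np.mean((ipred - dv) ** 2)))


def cohen_kappa(incl_a, incl_b) -> float:
    """Chance-corrected agreement between two inclusion patterns.

    ``incl_a`` and ``incl_b`` are boolean vectors over the same slot
    universe (e.g. all (parameter, covariate) pairs of a search space).
    Returns (p_o − p_e)/(1 − p_e); 1.0 when both patterns agree
    everywhere and chance agreement is also perfect.
    """
    a = np.asarray(incl_a, dtype=bool)
    b = np.asarray(incl_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inclusion vectors must be equal-length and non-empty")
    p_o = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    p_e = float(pa * pb + (1.0 - pa) * (1.0 - pb))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def median_pct_param_difference(params_a: dict, params_b: dict,
                                shared: list[str] | None = None,
                                reference: str = "a") -> float:
    """Median of 100·|a − b|/|reference| over shared parameter names.

    Parameters with a zero reference value are skipped.  ``reference``
    selects which model's values anchor the percentages (the comparator
    convention uses the stepwise model).
    """
    if shared is None:
        shared = sorted(set(params_a) & set(params_b))
    if not shared:
        raise ValueError("no shared parameters to compare")
    diffs = []
    for name in shared:
        ref = params_a[name] if reference == "a" else params_b[name]
        if ref == 0:
            continue
        diffs.append(100.0 * abs(params_a[name] - params_b[name]) / abs(ref))
    if not diffs:
        raise ValueError("all shared parameters had zero reference values")
    return float(np.median(diffs))


@dataclass
class ModelSummary:
    """Per-model fit statistics entering a comparison."""

    name: str
    obv: float
    k: int
    n: int
    mpe: float | None = None
    rmse: float | None = None

    @property
    def aic(self) -> float:
        return aic(self.obv, self.k)

    @property
    def bic(self) -> float:
        return bic(self.obv, self.k, self.n)


@dataclass
class ComparisonReport:
    """Head-to-head comparison of two selected models.

    ``delta_aic`` is model_b − model_a (negative favors b);
    ``kappa_covariates`` measures agreement of covariate inclusion over a
    shared slot universe, ``kappa_variability`` the same for IIV terms;
    ``median_pct_diff`` is the median absolute percent difference of
    shared parameters with model_a as the reference.
    """

    model_a: ModelSummary
    model_b: ModelSummary
    delta_aic: float
    kappa_covariates: float | None = None
    kappa_variability: float | None = None
    median_pct_diff: float | None = None


def compare_models(a: ModelSummary, b: ModelSummary,
                   covariate_slots_a=None, covariate_slots_b=None,
                   variability_slots_a=None, variability_slots_b=None,
                   params_a: dict | None = None,
                   params_b: dict | None = None) -> ComparisonReport:
    """Assemble a :class:`ComparisonReport` from fit summaries.

    Slot arguments are boolean inclusion vectors over the same decision
    universe (e.g. every (parameter, covariate) pair of the search
    space); parameter dicts enable the median percent difference.
    """
    report = ComparisonReport(model_a=a, model_b=b, delta_aic=b.aic - a.aic)
    if covariate_slots_a is not None and covariate_slots_b is not None:
        report.kappa_covariates = cohen_kappa(covariate_slots_a, covariate_slots_b)
    if variability_slots_a is not None and variability_slots_b is not None:
        report.kappa_variability = cohen_kappa(variability_slots_a, variability_slots_b)
    if params_a and params_b and set(params_a) & set(params_b):
        report.median_pct_diff = median_pct_param_difference(params_a, params_b)
    return report
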