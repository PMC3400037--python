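"""Candidate-model specification: covariate effects, IIV, residual error.

A :class:`ModelSpec` bundles every decision the search makes about one
candidate — structural kind, an *ordered* list of covariate effects with
their functional forms, which structural parameters carry
inter-individual variability (IIV), the residual-error form, and the
initial estimates/bounds for everything estimated.

Continuous covariate forms (x̃ is the reference, by default the
per-subject median of the covariate):

========  =======================================
add       TV + (x − x̃)·θ
prop      TV·(1 + θ·x/x̃)
exp       TV·exp(θ·x/x̃)
pow       TV·(x/x̃)^θ
mm        TV·θ₁·(x/x̃) / (θ₂ + x/x̃)
========  =======================================

Discrete forms sum indicator terms over the non-reference categories
(category 1 is the reference):

========  =======================================
add_d     TV + Σ_{k≥2} 1(x = k)·θ_k
prop_d    TV·(1 + Σ_{k≥2} 1(x = k)·θ_k)
exp_d     TV·exp(Σ_{k≥2} 1(x = k)·θ_k)
========  =======================================

Effects apply sequentially in list order starting from the covariate-free
typical value; order matters for chains mixing additive and
multiplicative forms, and the engine always uses the genome's slot order.

IIV is diagonal: CL_i = TVCL_i·exp(η_i) with η ~ N(0, ω²); ω is stored
as a standard deviation (reported as 100·ω %).  The ``additive`` IIV
kind (CL_i = TVCL_i + η_i) exists for the ``linear_test`` validation
model.  Residual-error variances σ² are stored as variances:
additive σ₁², proportional F²·σ₁², combined F²·σ₁² + σ₂².
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .structural import PARAM_NAMES

__all__ = [
    "CovariateEffect",
    "ModelSpec",
    "ParameterVector",
    "CONTINUOUS_FORMS",
    "DISCRETE_FORMS",
    "typical_value",
    "individual_parameter",
    "residual_variance",
    "count_penalized_parameters",
    "total_parameter_count",
]

CONTINUOUS_FORMS = ("add", "prop", "exp", "pow", "mm")
DISCRETE_FORMS = ("add_d", "prop_d", "exp_d")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate relationship on one structural parameter.

    ``reference`` is the median covariate value for continuous kinds, or
    the ordered category labels (reference category first) for discrete
    kinds.  ``n_thetas`` is 2 for ``mm``, one per non-reference category
    for discrete kinds, else 1.
    """

    target: str
    covariate: str
    kind: str
    reference: float | tuple = 1.0
    n_categories: int = 2

    def __post_init__(self) -> None:
        if self.kind not in CONTINUOUS_FORMS + DISCRETE_FORMS:
            raise ValueError(f"unknown covariate form {self.kind!r}")
        if self.kind in CONTINUOUS_FORMS and not self.reference > 0:
            raise ValueError("continuous forms scale by the reference; it must be > 0")
        if self.kind in DISCRETE_FORMS and self.n_categories < 2:
            raise ValueError("discrete forms need >= 2 categories")

    @property
    def n_thetas(self) -> int:
        if self.kind == "mm":
            return 2
        if self.kind in DISCRETE_FORMS:
            return self.n_categories - 1
        return 1

    @property
    def theta_names(self) -> tuple[str, ...]:
        stem = f"beta_{self.target}_{self.covariate}_{self.kind}"
        if self.n_thetas == 1:
            return (stem,)
        return tuple(f"{stem}_{i + 1}" for i in range(self.n_thetas))

    def apply(self, tv, x, thetas):
        """Apply this effect to typical value(s) ``tv`` given covariate
        value(s) ``x``; vectorized over subjects."""
        tv = np.asarray(tv, dtype=float)
        x = np.asarray(x, dtype=float)
        k = self.kind
        if k == "add":
            return tv + (x - self.reference) * thetas[0]
        if k == "prop":
            return tv * (1.0 + thetas[0] * x / self.reference)
        if k == "exp":
            return tv * np.exp(thetas[0] * x / self.reference)
        if k == "pow":
            return tv * (x / self.reference) ** thetas[0]
        if k == "mm":
            xr = x / self.reference
            return tv * thetas[0] * xr / (thetas[1] + xr)
        # discrete: category 1 is the reference, thetas index categories 2..K
        shift = np.zeros_like(tv)
        for j, th in enumerate(thetas):
            shift = shift + np.where(np.rint(x).astype(int) == j + 2, th, 0.0)
        if k == "add_d":
            return tv + shift
        if k == "prop_d":
            return tv * (1.0 + shift)
        return tv * np.exp(shift)  # exp_d


@dataclass
class ModelSpec:
    """A complete candidate model (structure + effects + variability)."""

    structural_kind: str
    effects: tuple[CovariateEffect, ...] = ()
    iiv: dict[str, str] = field(default_factory=dict)
    residual: str = "additive"
    initial: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.structural_kind not in PARAM_NAMES:
            raise ValueError(f"unknown structural kind {self.structural_kind!r}")
        if self.residual not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual kind {self.residual!r}")
        snames = PARAM_NAMES[self.structural_kind]
        for e in self.effects:
            if e.target not in snames:
                raise ValueError(f"effect targets unknown parameter {e.target!r}")
        for p, kind in self.iiv.items():
            if p not in snames:
                raise ValueError(f"IIV on unknown parameter {p!r}")
            if kind not in ("none", "exponential", "additive"):
                raise ValueError(f"unknown IIV kind {kind!r}")
        self.effects = tuple(self.effects)

    # --- parameter bookkeeping -------------------------------------------
    @property
    def structural_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.structural_kind]

    @property
    def covariate_theta_names(self) -> tuple[str, ...]:
        return tuple(n for e in self.effects for n in e.theta_names)

    @property
    def eta_params(self) -> tuple[str, ...]:
        """Structural parameters carrying a random effect, in model order."""
        return tuple(p for p in self.structural_names
                     if self.iiv.get(p, "none") != "none")

    @property
    def omega_names(self) -> tuple[str, ...]:
        return tuple(f"omega_{p}" for p in self.eta_params)

    @property
    def sigma_names(self) -> tuple[str, ...]:
        if self.residual == "additive":
            return ("sigma_add",)
        if self.residual == "proportional":
            return ("sigma_prop",)
        return ("sigma_prop", "sigma_add")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return (self.structural_names + self.covariate_theta_names
                + self.omega_names + self.sigma_names)

    def effects_on(self, target: str) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.effects if e.target == target)

    def with_effect(self, effect: CovariateEffect, initial=None, bounds=None) -> "ModelSpec":
        """A copy with one more effect appended (used by SCM and the GA)."""
        new = replace(self, effects=self.effects + (effect,),
                      initial=dict(self.initial), bounds=dict(self.bounds))
        for i, name in enumerate(effect.theta_names):
            new.initial.setdefault(name, (initial or {}).get(name, _default_theta_init(effect, i)))
            new.bounds.setdefault(name, (bounds or {}).get(name, _default_theta_bounds(effect, i)))
        return new

    def without_effect(self, index: int) -> "ModelSpec":
        eff = self.effects[index]
        keep = self.effects[:index] + self.effects[index + 1:]
        new = replace(self, effects=keep, initial=dict(self.initial), bounds=dict(self.bounds))
        for name in eff.theta_names:
            new.initial.pop(name, None)
            new.bounds.pop(name, None)
        return new

    def fill_defaults(self) -> "ModelSpec":
        """Populate any missing initial values/bounds with conventional defaults."""
        ini, bnd = dict(self.initial), dict(self.bounds)
        for name in self.structural_names:
            ini.setdefault(name, 1.0)
            bnd.setdefault(name, (1e-6, 1e6))
        for e in self.effects:
            for i, name in enumerate(e.theta_names):
                ini.setdefault(name, _default_theta_init(e, i))
                bnd.setdefault(name, _default_theta_bounds(e, i))
        for name in self.omega_names:
            ini.setdefault(name, 0.2)
            bnd.setdefault(name, (1e-4, 50.0))
        for name in self.sigma_names:
            ini.setdefault(name, 0.01 if name == "sigma_prop" else 0.01)
            bnd.setdefault(name, (1e-10, 1e4))
        return replace(self, initial=ini, bounds=bnd)

    def digest(self) -> str:
        """Stable hash of the model structure and initial estimates."""
        payload = {
            "kind": self.structural_kind,
            "effects": [(e.target, e.covariate, e.kind, e.reference, e.n_categories)
                        for e in self.effects],
            "iiv": sorted(self.iiv.items()),
            "residual": self.residual,
            "initial": sorted(self.initial.items()),
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _default_theta_init(effect: CovariateEffect, i: int) -> float:
    # the neutral point of each form: a newly added effect starts as a no-op
    if effect.kind == "mm":
        return 1.0
    return 0.0


def _default_theta_bounds(effect: CovariateEffect, i: int) -> tuple[float, float]:
    # covariates are scaled by their reference, so coefficients are O(1);
    # +/-10 already allows e^10-fold effects while keeping the search box sane
    if effect.kind == "mm":
        return (1e-6, 100.0)
    return (-10.0, 10.0)


@dataclass
class ParameterVector:
    """Estimates on the model (natural) scale, split NONMEM-style."""

    thetas: dict[str, float]
    omegas: dict[str, float]
    sigmas: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.omegas.values()):
            raise ValueError("omegas are standard deviations and must be >= 0")
        if any(v < 0 for v in self.sigmas.values()):
            raise ValueError("sigmas are variances and must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {**self.thetas, **self.omegas, **self.sigmas}


# --- the Table-4 computations -------------------------------------------

def typical_value(base: float, effects, covs: dict[str, float], thetas: dict[str, float]):
    """Covariate-adjusted typical value, applying ``effects`` sequentially.

    ``covs`` maps covariate name to this subject's value; ``thetas`` maps
    coefficient names to values.  A non-positive result is the caller's
    signal of an invalid evaluation (treated as an estimation failure
    during search, never an exception).
    """
    tv = float(base)
    for e in effects:
        th = [thetas[n] for n in e.theta_names]
        tv = float(e.apply(tv, covs[e.covariate], th))
    return tv


def individual_parameter(tv: float, iiv_kind: str, eta: float) -> float:
    """Subject-level parameter from its typical value and random effect."""
    if iiv_kind == "none":
        return tv
    if iiv_kind == "exponential":
        return tv * float(np.exp(eta))
    if iiv_kind == "additive":
        return tv + eta
    raise ValueError(f"unknown IIV kind {iiv_kind!r}")


def residual_variance(pred, residual_kind: str, sigmas: dict[str, float]):
    """Residual variance of an observation given its model prediction."""
    pred = np.asarray(pred, dtype=float)
    if residual_kind == "additive":
        return np.broadcast_to(np.asarray(sigmas["sigma_add"], dtype=float), pred.shape).copy()
    if residual_kind == "proportional":
        return pred ** 2 * sigmas["sigma_prop"]
    if residual_kind == "combined":
        return pred ** 2 * sigmas["sigma_prop"] + sigmas["sigma_add"]
    raise ValueError(f"unknown residual kind {residual_kind!r}")


def count_penalized_parameters(spec: ModelSpec) -> tuple[int, int, int]:
    """(covariate thetas, IIV terms, residual terms) — the parsimony-penalty base.

    Structural thetas are deliberately free: the fitness judges structure
    changes by OBV alone.
    """
    n_cov = sum(e.n_thetas for e in spec.effects)
    n_omega = len(spec.omega_names)
    n_sigma = len(spec.sigma_names)
    return n_cov, n_omega, n_sigma


def total_parameter_count(spec: ModelSpec) -> int:
    """k of AIC/BIC: every estimated quantity."""
    n_cov, n_omega, n_sigma = count_penalized_parameters(spec)
    return len(spec.structural_names) + n_cov + n_omega + n_sigma
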