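"""Automated stepwise covariate modeling (SCM).

Forward inclusion: every remaining (parameter, covariate, form)
candidate is added singly to the current model; the candidate giving the
largest objective drop is included, provided the drop reaches the
likelihood-ratio threshold chi²(1−p_in, df) with df equal to the number
of coefficients the candidate adds.  Backward elimination then removes,
one at a time, the included effect whose removal costs the least, as
long as that cost stays below chi²(1−p_out, df).  Ties break toward the
earlier-listed candidate and failed fits simply never qualify — the
search logs and skips them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .data_io import PKDataset
from .estimation import EstimationSettings, FitResult, fit_model
from .model_spec import CovariateEffect, ModelSpec

__all__ = [
    "SCMConfig",
    "SCMStep",
    "SCMTrace",
    "lrt_threshold",
    "forward_search",
    "backward_search",
    "run_scm",
]


@dataclass
class SCMConfig:
    p_in: float = 0.05
    p_out: float = 0.01
    candidates: tuple[CovariateEffect, ...] = ()
    estimation: EstimationSettings = field(default_factory=EstimationSettings)

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out):
            if not 0.0 < p < 1.0:
                raise ValueError("p_in and p_out must be in (0, 1)")
        self.candidates = tuple(self.candidates)


@dataclass
class SCMStep:
    phase: str               # "forward" | "backward"
    candidate: str           # "<target>~<covariate>:<form>"
    obv: float
    delta_obv: float         # vs the current model (signed)
    threshold: float
    decision: str            # "added" | "removed" | "rejected" | "kept" | "failed"


@dataclass
class SCMTrace:
    steps: list[SCMStep] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FitResult | None = None


def lrt_threshold(p: float, df: int = 1) -> float:
    """ΔOBV required at significance level ``p`` with ``df`` degrees of freedom."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - p, df))


def _label(e: CovariateEffect) -> str:
    return f"{e.target}~{e.covariate}:{e.kind}"


def _fit(spec: ModelSpec, ds: PKDataset, est: EstimationSettings,
         warm: FitResult | None) -> FitResult:
    spec = spec.fill_defaults()
    if warm is not None:
        ini = dict(spec.initial)
        fitted = warm.params.as_dict()
        for name in ini:
            if name in fitted:
                lo, hi = spec.bounds[name]
                ini[name] = min(max(fitted[name], lo * (1 + 1e-9)), hi * (1 - 1e-9))
        from dataclasses import replace
        spec = replace(spec, initial=ini, bounds=dict(spec.bounds))
    return fit_model(spec, ds, est)


def forward_search(base: ModelSpec, cfg: SCMConfig, ds: PKDataset,
                   base_fit: FitResult | None = None) -> tuple[ModelSpec, FitResult, SCMTrace]:
    """Greedy forward inclusion from ``base`` over ``cfg.candidates``."""
    est = cfg.estimation
    current = base.fill_defaults()
    current_fit = base_fit or _fit(current, ds, est, None)
    if not current_fit.converged:
        raise RuntimeError("base model fit did not converge; cannot start SCM")
    trace = SCMTrace()
    remaining = list(cfg.candidates)
    while remaining:
        best_i, best_fit, best_drop = None, None, 0.0
        for i, cand in enumerate(remaining):
            trial = current.with_effect(cand)
            fit = _fit(trial, ds, est, current_fit)
            thr = lrt_threshold(cfg.p_in, cand.n_thetas)
            if not fit.converged:
                trace.steps.append(SCMStep("forward", _label(cand), fit.obv,
                                           float("nan"), thr, "failed"))
                continue
            drop = current_fit.obv - fit.obv
            qualifies = drop >= thr
            trace.steps.append(SCMStep("forward", _label(cand), fit.obv,
                                       -drop, thr, "tested" if qualifies else "rejected"))
            # strictly-greater keeps the earlier-listed candidate on ties
            if qualifies and (best_i is None or drop > best_drop):
                best_i, best_fit, best_drop = i, fit, drop
        if best_i is None:
            break
        chosen = remaining.pop(best_i)
        current = current.with_effect(chosen)
        current_fit = best_fit
        trace.steps.append(SCMStep("forward", _label(chosen), best_fit.obv,
                                   -best_drop, lrt_threshold(cfg.p_in, chosen.n_thetas),
                                   "added"))
    trace.final_spec, trace.final_fit = current, current_fit
    return current, current_fit, trace


def backward_search(full: ModelSpec, cfg: SCMConfig, ds: PKDataset,
                    full_fit: FitResult | None = None) -> tuple[ModelSpec, FitResult, SCMTrace]:
    """Backward elimination of the effects present in ``full``."""
    est = cfg.estimation
    current = full.fill_defaults()
    current_fit = full_fit or _fit(current, ds, est, None)
    trace = SCMTrace()
    while current.effects:
        best_i, best_fit, best_rise = None, None, float("inf")
        for i, eff in enumerate(current.effects):
            reduced = current.without_effect(i)
            fit = _fit(reduced, ds, est, current_fit)
            thr = lrt_threshold(cfg.p_out, eff.n_thetas)
            if not fit.converged:
                trace.steps.append(SCMStep("backward", _label(eff), fit.obv,
                                           float("nan"), thr, "failed"))
                continue
            rise = fit.obv - current_fit.obv
            removable = rise < thr
            trace.steps.append(SCMStep("backward", _label(eff), fit.obv, rise, thr,
                                       "tested" if removable else "kept"))
            if removable and rise < best_rise:
                best_i, best_fit, best_rise = i, fit, rise
        if best_i is None:
            break
        removed = current.effects[best_i]
        current = current.without_effect(best_i)
        current_fit = best_fit
        trace.steps.append(SCMStep("backward", _label(removed), best_fit.obv,
                                   best_rise, lrt_threshold(cfg.p_out, removed.n_thetas),
                                   "removed"))
    trace.final_spec, trace.final_fit = current, current_fit
    return current, current_fit, trace


def run_scm(base: ModelSpec, cfg: SCMConfig, ds: PKDataset,
            base_fit: FitResult | None = None) -> tuple[ModelSpec, FitResult, SCMTrace]:
    """Forward inclusion followed by backward elimination; traces concatenated."""
    fwd_spec, fwd_fit, fwd_trace = forward_search(base, cfg, ds, base_fit)
    final_spec, final_fit, bwd_trace = backward_search(fwd_spec, cfg, ds, fwd_fit)
    trace = SCMTrace(steps=fwd_trace.steps + bwd_trace.steps,
                     final_spec=final_spec, final_fit=final_fit)
    return final_spec, final_fit, trace
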