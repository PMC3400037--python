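"""The single-objective hybrid genetic algorithm (SOHGA).

A candidate's fitness is its objective value plus penalties:

* parsimony — 10 points (configurable; 3.84 is the likelihood-ratio
  alternative) per covariate coefficient, IIV term and residual-error
  term; structural parameters are free, so structure changes compete on
  OBV alone;
* 400 points, applied once, if the minimization or the covariance step
  failed;
* 300 points if any off-diagonal of the estimation correlation matrix
  exceeds 0.95 in absolute value (skipped when no correlation matrix
  exists — the 400 penalty already covers that case);
* an optional 300 points when the condition number exceeds 1,000
  (disabled by default, matching a planned-versus-post-hoc distinction
  in how such diagnostics are typically used);
* a niche penalty for candidates within a small Hamming distance of a
  better candidate, preserving population diversity.

Selection is roulette-wheel on *scaled* fitness: a linear map fitted to
the values within two standard deviations of the population mean sends
the best in-window fitness to weight 4 and the worst to 0.2, with
outliers clamped to those extremes, so a single disastrous candidate
cannot flatten the selection pressure.

Every fifth generation (configurable) a one-bit-flip downhill search
refines the best genome of each niche until no single-bit change
improves the fitness.  The best candidate overall survives unchanged
between generations (elitism).  All fits are cached by genome and by
decoded-model digest, and the whole run is a deterministic function of
(search space, dataset, configuration, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace as _dc_replace

import numpy as np

from .data_io import PKDataset
from .estimation import EstimationSettings, FitResult, fit_model
from .genome import SearchSpace, crossover, decode, mutate, hamming, one_bit_neighbors, random_genome
from .model_spec import ModelSpec, count_penalized_parameters

__all__ = [
    "GAConfig",
    "FitnessComponents",
    "CandidateRecord",
    "RunLog",
    "evaluate_fitness",
    "scale_fitness",
    "select_parents",
    "assign_niches",
    "downhill_search",
    "step_generation",
    "run_sohga",
    "GAState",
]


@dataclass
class GAConfig:
    pop_size: int = 200
    generations: int = 40
    crossover_prob: float = 0.7
    mutation_rate: float = 0.01
    parsimony_penalty: float = 10.0
    nonconvergence_penalty: float = 400.0
    correlation_penalty: float = 300.0
    correlation_threshold: float = 0.95
    condition_penalty: float = 300.0
    condition_threshold: float = 1000.0
    condition_penalty_enabled: bool = False
    niche_distance: int = 4
    n_niches: int = 4
    niche_penalty: float = 200.0
    downhill_period: int = 5
    downhill_budget: int | None = None
    scale_bounds: tuple[float, float] = (0.2, 4.0)
    fit_timeout: float = 60.0
    generation_timeout: float = 600.0
    failure_obv: float = 1e6
    seed: int = 0
    seed_base_genome: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 2 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 2")
        if not 0.0 < self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in (0, 1]")
        for name in ("parsimony_penalty", "nonconvergence_penalty",
                     "correlation_penalty", "condition_penalty", "niche_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FitnessComponents:
    obv: float
    parsimony: float = 0.0
    nonconvergence: float = 0.0
    correlation: float = 0.0
    condition: float = 0.0
    niche: float = 0.0

    @property
    def total(self) -> float:
        return (self.obv + self.parsimony + self.nonconvergence
                + self.correlation + self.condition + self.niche)


@dataclass
class CandidateRecord:
    genome: str
    spec_digest: str
    obv: float
    converged: bool
    covariance_success: bool
    max_offdiag_correlation: float | None
    condition_number: float | None
    fitness: FitnessComponents
    generation: int
    niche_id: int = -1


@dataclass
class RunLog:
    config: dict
    seed: int
    records: list[CandidateRecord] = field(default_factory=list)
    generation_best: list[float] = field(default_factory=list)
    best_genome: str | None = None
    best_fitness: float = float("inf")
    best_per_niche: list[tuple[str, float]] = field(default_factory=list)
    wall_time: float = 0.0
    n_fits: int = 0

    def to_jsonl(self, sink) -> None:
        header = {"config": self.config, "seed": self.seed,
                  "wall_time": self.wall_time, "n_fits": self.n_fits,
                  "best_genome": self.best_genome, "best_fitness": self.best_fitness}
        sink.write(json.dumps({"run": header}, default=float) + "\n")
        for rec in self.records:
            d = asdict(rec)
            d["fitness"]["total"] = rec.fitness.total
            sink.write(json.dumps(d, default=float) + "\n")


def evaluate_fitness(fit: FitResult, spec: ModelSpec, cfg: GAConfig) -> FitnessComponents:
    """Penalized fitness of one evaluated candidate (niche term added later)."""
    n_cov, n_omega, n_sigma = count_penalized_parameters(spec)
    parsimony = cfg.parsimony_penalty * (n_cov + n_omega + n_sigma)
    obv = fit.obv if np.isfinite(fit.obv) else cfg.failure_obv
    failed = (not fit.converged) or (not fit.covariance_success)
    nonconvergence = cfg.nonconvergence_penalty if failed else 0.0
    correlation = 0.0
    condition = 0.0
    if fit.covariance_success and fit.correlation is not None:
        if fit.max_offdiag_correlation > cfg.correlation_threshold:
            correlation = cfg.correlation_penalty
        if (cfg.condition_penalty_enabled and fit.condition_number is not None
                and fit.condition_number > cfg.condition_threshold):
            condition = cfg.condition_penalty
    return FitnessComponents(obv=obv, parsimony=parsimony,
                             nonconvergence=nonconvergence,
                             correlation=correlation, condition=condition)


def scale_fitness(totals, bounds: tuple[float, float] = (0.2, 4.0)) -> np.ndarray:
    """Selection weights from raw fitness totals (lower fitness -> higher weight).

    A linear map over the values within two standard deviations of the
    mean sends the in-window best to ``bounds[1]`` and worst to
    ``bounds[0]``; values outside the window clamp to the corresponding
    extreme.  A spread-free population gets uniform weight 1.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        raise ValueError("empty population")
    lo_w, hi_w = bounds
    mean = totals.mean()
    sd = totals.std(ddof=1) if totals.size > 1 else 0.0
    if sd == 0.0:
        return np.ones_like(totals)
    window = np.abs(totals - mean) <= 2.0 * sd
    win = totals[window]
    wmin, wmax = win.min(), win.max()
    weights = np.empty_like(totals)
    if wmax == wmin:
        weights[window] = 1.0
    else:
        # best (lowest) fitness -> hi_w, worst -> lo_w
        weights[window] = hi_w + (win - wmin) * (lo_w - hi_w) / (wmax - wmin)
    weights[~window & (totals < mean)] = hi_w
    weights[~window & (totals >= mean)] = lo_w
    return weights


def select_parents(weights, rng: np.random.Generator, n_pairs: int) -> list[tuple[int, int]]:
    """Roulette sampling of parent index pairs, proportional to weights."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    p = weights / weights.sum()
    idx = rng.choice(weights.size, size=2 * n_pairs, p=p)
    return [(int(idx[2 * i]), int(idx[2 * i + 1])) for i in range(n_pairs)]


def assign_niches(genomes: list[str], totals, cfg: GAConfig):
    """Greedy leader clustering by fitness order.

    The best unassigned candidate seeds a niche; every unassigned
    candidate within ``niche_distance`` (Hamming) joins it.  Non-leader
    members get the niche penalty, as do leaders of niches beyond the
    first ``n_niches`` (the protected regions of the search space).
    Returns (niche ids, penalty per candidate, leader indices).
    """
    n = len(genomes)
    order = np.argsort(np.asarray(totals, dtype=float), kind="stable")
    niche_id = np.full(n, -1, dtype=int)
    penalty = np.zeros(n)
    leaders: list[int] = []
    for i in order:
        if niche_id[i] >= 0:
            continue
        nid = len(leaders)
        leaders.append(int(i))
        niche_id[i] = nid
        for j in order:
            if niche_id[j] < 0 and hamming(genomes[i], genomes[j]) <= cfg.niche_distance:
                niche_id[j] = nid
                penalty[j] = cfg.niche_penalty
        if nid >= cfg.n_niches:
            penalty[i] = cfg.niche_penalty
    return niche_id, penalty, leaders


def downhill_search(genome: str, evaluator, budget: int | None = None) -> tuple[str, float]:
    """One-bit-flip local refinement.

    Repeatedly evaluates all single-bit neighbors and moves to the best
    strictly improving one, until a local optimum (or the evaluation
    budget) is reached.  ``evaluator(genome) -> total fitness`` is
    expected to cache.  The returned fitness never exceeds the input's.
    """
    current = genome
    current_fit = evaluator(current)
    used = 0
    while True:
        best_n, best_f = None, current_fit
        for nb in one_bit_neighbors(current):
            if budget is not None and used >= budget:
                return current, current_fit
            f = evaluator(nb)
            used += 1
            if f < best_f:
                best_n, best_f = nb, f
        if best_n is None:
            return current, current_fit
        current, current_fit = best_n, best_f


@dataclass
class GAState:
    space: SearchSpace
    ds: PKDataset
    cfg: GAConfig
    est: EstimationSettings
    rng: np.random.Generator
    population: list[str] = field(default_factory=list)
    fitness: list[FitnessComponents] = field(default_factory=list)
    niche_ids: np.ndarray | None = None
    leaders: list[int] = field(default_factory=list)
    cache: dict[str, tuple[FitnessComponents, FitResult]] = field(default_factory=dict)
    spec_cache: dict[str, tuple[FitnessComponents, FitResult]] = field(default_factory=dict)
    log: RunLog | None = None
    generation: int = 0
    base_initials: dict | None = None
    fitness_fn: object = None  # optional genome -> FitnessComponents override

    def evaluate(self, genome: str, deadline: float | None = None) -> FitnessComponents:
        """Fitness of one genome, with genome- and model-digest-level caching."""
        hit = self.cache.get(genome)
        if hit is not None:
            return _dc_replace(hit[0], niche=0.0)
        if self.fitness_fn is not None:
            comp = self.fitness_fn(genome)
            fit = FitResult(params=None, obv=comp.obv, converged=True,
                            covariance_success=True)
            self.cache[genome] = (comp, fit)
            self.log.n_fits += 1
            self.log.records.append(CandidateRecord(
                genome=genome, spec_digest="", obv=comp.obv, converged=True,
                covariance_success=True, max_offdiag_correlation=None,
                condition_number=None, fitness=comp, generation=self.generation))
            return _dc_replace(comp, niche=0.0)
        spec = decode(genome, self.space)
        if self.base_initials:
            ini = dict(spec.initial)
            for k, v in self.base_initials.items():
                if k in ini:
                    ini[k] = v
            spec = _respec_initial(spec, ini)
        digest = spec.digest()
        hit = self.spec_cache.get(digest)
        if hit is None:
            est = self.est
            if deadline is not None:
                remaining = max(deadline - time.monotonic(), 1e-3)
                if remaining < est.timeout:
                    est = _with_timeout(est, remaining)
            fit = fit_model(spec, self.ds, est)
            comp = evaluate_fitness(fit, spec, self.cfg)
            self.log.n_fits += 1
            hit = (comp, fit)
            self.spec_cache[digest] = hit
        comp, fit = hit
        self.cache[genome] = hit
        self.log.records.append(CandidateRecord(
            genome=genome, spec_digest=digest, obv=fit.obv,
            converged=fit.converged, covariance_success=fit.covariance_success,
            max_offdiag_correlation=fit.max_offdiag_correlation,
            condition_number=fit.condition_number,
            fitness=comp, generation=self.generation,
        ))
        # a fresh copy: niche penalties are per-population-slot, not cached
        return _dc_replace(comp, niche=0.0)

    def best(self) -> tuple[str, float]:
        totals = [f.total for f in self.fitness]
        i = int(np.argmin(totals))
        return self.population[i], totals[i]


def _respec_initial(spec: ModelSpec, initial: dict) -> ModelSpec:
    from dataclasses import replace
    return replace(spec, initial=initial, bounds=dict(spec.bounds))


def _with_timeout(est: EstimationSettings, timeout: float) -> EstimationSettings:
    from dataclasses import replace
    return replace(est, timeout=timeout)


def _evaluate_population(state: GAState, genomes: list[str]) -> list[FitnessComponents]:
    deadline = time.monotonic() + state.cfg.generation_timeout
    comps = []
    for g in genomes:
        if time.monotonic() > deadline:
            # generation timed out: remaining candidates are marked failed
            comps.append(FitnessComponents(
                obv=state.cfg.failure_obv,
                nonconvergence=state.cfg.nonconvergence_penalty))
            continue
        comps.append(state.evaluate(g, deadline))
    return comps


def _apply_niches(state: GAState) -> None:
    totals = [c.total - c.niche for c in state.fitness]  # niche-free totals
    niche_ids, penalties, leaders = assign_niches(state.population, totals, state.cfg)
    for c, pen in zip(state.fitness, penalties):
        c.niche = float(pen)
    state.niche_ids = niche_ids
    state.leaders = leaders


def step_generation(state: GAState) -> GAState:
    """One GA generation: selection, crossover, mutation, evaluation,
    niching, elitism."""
    cfg, rng = state.cfg, state.rng
    elite_genome, elite_fit = state.best()
    weights = scale_fitness([c.total for c in state.fitness], cfg.scale_bounds)
    pairs = select_parents(weights, rng, cfg.pop_size // 2)
    children: list[str] = []
    for i, j in pairs:
        a, b = state.population[i], state.population[j]
        if rng.random() < cfg.crossover_prob:
            a, b = crossover(a, b, rng)
        children.append(mutate(a, cfg.mutation_rate, rng))
        children.append(mutate(b, cfg.mutation_rate, rng))
    state.generation += 1
    comps = _evaluate_population(state, children)
    state.population, state.fitness = children, comps
    # elitism: the best genome so far re-enters unchanged, replacing the worst
    if elite_genome not in state.population:
        worst = int(np.argmax([c.total for c in state.fitness]))
        state.population[worst] = elite_genome
        state.fitness[worst] = state.evaluate(elite_genome)
    _apply_niches(state)
    return state


def run_sohga(space: SearchSpace, ds: PKDataset | None, cfg: GAConfig,
              est: EstimationSettings | None = None,
              base_initials: dict | None = None,
              fitness_fn=None) -> RunLog:
    """Run the full hybrid GA and return its complete run log.

    ``base_initials`` optionally overrides initial estimates of
    parameters shared with a previously fitted base model, which warm
    starts every candidate fit.  ``fitness_fn`` replaces the
    fit-and-penalize pipeline with a direct genome -> FitnessComponents
    map (toy problems, calibration studies).
    """
    est = est or EstimationSettings()
    if est.timeout > cfg.fit_timeout:
        est = _with_timeout(est, cfg.fit_timeout)
    rng = np.random.default_rng(cfg.seed)
    log = RunLog(config={**asdict(cfg)}, seed=cfg.seed)
    state = GAState(space=space, ds=ds, cfg=cfg, est=est, rng=rng, log=log,
                    base_initials=base_initials, fitness_fn=fitness_fn)
    t0 = time.monotonic()
    L = space.total_bits
    population = [random_genome(L, rng) for _ in range(cfg.pop_size)]
    if cfg.seed_base_genome:
        population[0] = "0" * L
    state.population = population
    state.fitness = _evaluate_population(state, population)
    _apply_niches(state)
    log.generation_best.append(state.best()[1])
    _track_best(state)
    for gen in range(1, cfg.generations + 1):
        step_generation(state)
        if cfg.downhill_period and gen % cfg.downhill_period == 0:
            _downhill_on_niches(state)
        log.generation_best.append(state.best()[1])
        _track_best(state)
    log.best_per_niche = _final_niche_best(state)
    log.wall_time = time.monotonic() - t0
    return log


def _track_best(state: GAState) -> None:
    g, f = state.best()
    if f < state.log.best_fitness:
        state.log.best_fitness = f
        state.log.best_genome = g


def _downhill_on_niches(state: GAState) -> None:
    """Refine the best genome of each niche by one-bit downhill search."""
    cfg = state.cfg

    def evaluator(g: str) -> float:
        return state.evaluate(g).total

    for leader in list(state.leaders)[:cfg.n_niches]:
        genome = state.population[leader]
        refined, fit = downhill_search(genome, evaluator, cfg.downhill_budget)
        if refined != genome and fit < state.fitness[leader].total:
            state.population[leader] = refined
            state.fitness[leader] = state.evaluate(refined)
    _apply_niches(state)


def _final_niche_best(state: GAState) -> list[tuple[str, float]]:
    best: dict[int, tuple[str, float]] = {}
    for g, c, nid in zip(state.population, state.fitness, state.niche_ids):
        nid = int(nid)
        if nid not in best or c.total < best[nid][1]:
            best[nid] = (g, c.total)
    return [best[k] for k in sorted(best)]
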