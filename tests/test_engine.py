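import numpy as np
import pytest

from sohga.engine import (
    FitnessComponents, GAConfig, assign_niches, downhill_search,
    evaluate_fitness, run_sohga, scale_fitness, select_parents,
)
from sohga.estimation import FitResult
from sohga.genome import DecisionSlot, SearchSpace, hamming, random_genome
from sohga.model_spec import CovariateEffect, ModelSpec, ParameterVector


def fit_result(obv=1000.0, converged=True, cov_success=True, max_corr=0.5,
               condition=100.0):
    n = 2 + int(max_corr is not None)
    corr = np.eye(2)
    corr[0, 1] = corr[1, 0] = max_corr
    return FitResult(
        params=ParameterVector({}, {}, {}), obv=obv, converged=converged,
        covariance_success=cov_success,
        correlation=corr if cov_success else None,
        condition_number=condition if cov_success else None,
    )


def six_param_spec():
    # 2 covariate thetas + 2 omegas + 2 sigmas penalized
    return ModelSpec(
        "onecpt_iv",
        effects=(CovariateEffect("CL", "WT", "exp", reference=70.0),
                 CovariateEffect("V", "WT", "exp", reference=70.0)),
        iiv={"CL": "exponential", "V": "exponential"},
        residual="combined",
    ).fill_defaults()


class TestEvaluateFitness:
    def setup_method(self):
        self.cfg = GAConfig(pop_size=30, generations=2)
        self.spec = six_param_spec()

    def test_parsimony_only(self):
        comp = evaluate_fitness(fit_result(obv=1000.0), self.spec, self.cfg)
        assert comp.parsimony == 60.0
        assert comp.total == 1060.0

    def test_nonconvergence_penalty(self):
        comp = evaluate_fitness(fit_result(obv=1000.0, converged=False),
                                self.spec, self.cfg)
        assert comp.nonconvergence == 400.0
        assert comp.total == 1460.0

    def test_failed_covariance_same_single_penalty(self):
        comp = evaluate_fitness(
            fit_result(obv=1000.0, converged=False, cov_success=False),
            self.spec, self.cfg)
        assert comp.nonconvergence == 400.0  # one penalty, two triggers
        assert comp.total == 1460.0

    def test_correlation_penalty_above_095(self):
        comp = evaluate_fitness(fit_result(obv=1000.0, max_corr=0.96),
                                self.spec, self.cfg)
        assert comp.correlation == 300.0
        assert comp.total == 1360.0

    def test_correlation_at_threshold_not_penalized(self):
        comp = evaluate_fitness(fit_result(obv=1000.0, max_corr=0.95),
                                self.spec, self.cfg)
        assert comp.correlation == 0.0

    def test_condition_penalty_disabled_by_default(self):
        comp = evaluate_fitness(fit_result(obv=1000.0, condition=2830.0),
                                self.spec, self.cfg)
        assert comp.condition == 0.0

    def test_condition_penalty_when_enabled(self):
        cfg = GAConfig(pop_size=30, generations=2, condition_penalty_enabled=True)
        comp = evaluate_fitness(fit_result(obv=1000.0, condition=2830.0),
                                self.spec, cfg)
        assert comp.condition == 300.0
        assert comp.total == 1360.0

    def test_total_is_sum_of_components(self):
        cfg = GAConfig(pop_size=30, generations=2, condition_penalty_enabled=True)
        comp = evaluate_fitness(
            fit_result(obv=1000.0, converged=False, cov_success=False), self.spec, cfg)
        assert comp.total == (comp.obv + comp.parsimony + comp.nonconvergence
                              + comp.correlation + comp.condition + comp.niche)


class TestScaleFitness:
    def test_two_values_hit_the_extremes(self):
        np.testing.assert_allclose(scale_fitness([10.0, 20.0]), [4.0, 0.2])

    def test_equal_values_get_unit_weight(self):
        np.testing.assert_allclose(scale_fitness([7.0, 7.0, 7.0]), [1.0, 1.0, 1.0])

    def test_far_outlier_clamped_to_low_extreme(self):
        w = scale_fitness([0.0, 10.0, 20.0, 1e9])
        assert w[3] == pytest.approx(0.2)
        assert w[0] == pytest.approx(4.0)

    def test_monotone_nonincreasing_in_fitness(self):
        totals = [5.0, 1.0, 3.0, 100.0, 2.0]
        w = scale_fitness(totals)
        order = np.argsort(totals)
        assert all(w[order[i]] >= w[order[i + 1]] for i in range(len(totals) - 1))

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            scale_fitness([])


class TestSelectParents:
    def test_roulette_frequencies(self):
        rng = np.random.default_rng(0)
        pairs = select_parents([4.0, 0.2], rng, 50_000)
        draws = np.array([i for p in pairs for i in p])
        p_hat = np.mean(draws == 0)
        p_true = 4.0 / 4.2
        assert abs(p_hat - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / draws.size)

    def test_single_positive_weight_always_chosen(self):
        rng = np.random.default_rng(1)
        pairs = select_parents([0.0, 5.0, 0.0], rng, 100)
        assert all(p == (1, 1) for p in pairs)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            select_parents([0.0, 0.0], np.random.default_rng(0), 5)


class TestAssignNiches:
    def setup_method(self):
        self.cfg = GAConfig(pop_size=30, generations=1, niche_distance=4,
                            n_niches=4, niche_penalty=200.0)

    def test_identical_genomes_one_niche(self):
        genomes = ["0101"] * 5
        ids, pen, leaders = assign_niches(genomes, [3.0, 1.0, 2.0, 5.0, 4.0], self.cfg)
        assert len(set(ids)) == 1
        assert pen[1] == 0.0                      # best is the leader
        assert sum(p > 0 for p in pen) == 4

    def test_distant_genomes_separate_niches(self):
        genomes = ["0000000", "1111111"]          # Hamming 7 > 4
        ids, pen, leaders = assign_niches(genomes, [1.0, 2.0], self.cfg)
        assert ids[0] != ids[1]
        assert list(pen) == [0.0, 0.0]

    def test_four_mutually_distant_genomes_unpenalized(self):
        genomes = ["0000000000", "1111100000", "0000011111", "1111111111"]
        ids, pen, leaders = assign_niches(genomes, [1.0, 2.0, 3.0, 4.0], self.cfg)
        assert len(set(ids)) == 4
        assert not any(pen)

    def test_surplus_leaders_penalized(self):
        cfg = GAConfig(pop_size=30, generations=1, niche_distance=1,
                       n_niches=2, niche_penalty=50.0)
        genomes = ["000000", "111111", "101010"]  # three mutually distant
        ids, pen, leaders = assign_niches(genomes, [1.0, 2.0, 3.0], cfg)
        assert len(set(ids)) == 3
        assert pen[2] == 50.0 and pen[0] == 0.0 and pen[1] == 0.0


def bitcount_evaluator(target="111"):
    """Toy fitness: Hamming distance to the target bit string."""
    calls = []

    def ev(g):
        calls.append(g)
        return float(hamming(g, target))

    ev.calls = calls
    return ev


class TestDownhill:
    def test_reaches_unique_optimum(self):
        ev = bitcount_evaluator("111")
        g, f = downhill_search("000", ev)
        assert g == "111" and f == 0.0

    def test_local_optimum_returned_unchanged(self):
        ev = bitcount_evaluator("010")
        g, f = downhill_search("010", ev)
        assert g == "010" and f == 0.0

    def test_never_worsens(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            start = random_genome(8, rng)
            ev = bitcount_evaluator("10110101")
            f0 = ev(start)
            _, f = downhill_search(start, ev)
            assert f <= f0

    def test_one_sweep_evaluates_l_neighbors(self):
        # at a local optimum a single sweep touches exactly L candidates
        g = "1" * 40
        ev = bitcount_evaluator("1" * 40)
        downhill_search(g, ev)
        assert len(ev.calls) == 1 + 40  # the start plus its 40 one-bit neighbors

    def test_budget_respected(self):
        ev = bitcount_evaluator("1" * 20)
        downhill_search("0" * 20, ev, budget=7)
        assert len(ev.calls) <= 1 + 7


def toy_space(n_slots=6):
    slots = tuple(DecisionSlot(f"s{i}", (0, 1)) for i in range(n_slots))
    return SearchSpace(slots=slots, assemble=lambda picked: ModelSpec("onecpt_iv"))


def toy_fitness(target):
    def fn(genome):
        return FitnessComponents(obv=float(hamming(genome, target)))
    return fn


class TestRunSohga:
    def test_finds_toy_optimum(self):
        space = toy_space(6)
        cfg = GAConfig(pop_size=10, generations=6, downhill_period=2,
                       niche_penalty=0.5, seed=3, seed_base_genome=False)
        log = run_sohga(space, None, cfg, fitness_fn=toy_fitness("101101"))
        assert log.best_genome == "101101"
        assert log.best_fitness == 0.0

    def test_generation_best_non_increasing(self):
        space = toy_space(8)
        cfg = GAConfig(pop_size=12, generations=8, seed=4)
        log = run_sohga(space, None, cfg, fitness_fn=toy_fitness("10110101"))
        assert all(a >= b for a, b in zip(log.generation_best, log.generation_best[1:]))

    def test_zero_generations_only_initial_population(self):
        space = toy_space(4)
        cfg = GAConfig(pop_size=6, generations=0, seed=5)
        log = run_sohga(space, None, cfg, fitness_fn=toy_fitness("1010"))
        assert len(log.generation_best) == 1
        assert {r.generation for r in log.records} == {0}

    def test_seeded_runs_are_bit_reproducible(self):
        space = toy_space(8)
        cfg = GAConfig(pop_size=10, generations=5, downhill_period=2, seed=11)
        a = run_sohga(space, None, cfg, fitness_fn=toy_fitness("11001100"))
        b = run_sohga(space, None, cfg, fitness_fn=toy_fitness("11001100"))
        assert a.best_genome == b.best_genome
        assert [r.genome for r in a.records] == [r.genome for r in b.records]
        assert [r.fitness.total for r in a.records] == [r.fitness.total for r in b.records]

    def test_records_satisfy_total_identity(self):
        space = toy_space(6)
        cfg = GAConfig(pop_size=8, generations=4, seed=6)
        log = run_sohga(space, None, cfg, fitness_fn=toy_fitness("111000"))
        for r in log.records:
            f = r.fitness
            assert f.total == (f.obv + f.parsimony + f.nonconvergence
                               + f.correlation + f.condition + f.niche)

    def test_cached_genome_fitness_identical(self):
        space = toy_space(5)
        cfg = GAConfig(pop_size=8, generations=6, seed=7)
        log = run_sohga(space, None, cfg, fitness_fn=toy_fitness("10101"))
        seen = {}
        for r in log.records:
            if r.genome in seen:
                assert r.fitness.total == seen[r.genome]
            seen[r.genome] = r.fitness.total


class TestGAConfigValidation:
    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(pop_size=31)

    def test_zero_crossover_prob_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(crossover_prob=0.0)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(niche_penalty=-1.0)
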