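import numpy as np
import pytest

from froghop import (
    FeatureWeights,
    Frog,
    SFLAConfig,
    improve_worst_frog,
    leap_features,
    leap_size,
    partition_memplexes,
    run,
    sample_submemplex,
    submemplex_probability,
    subset_samples,
)
from froghop.sfla_engine import SearchContext, sort_by_fitness, worst_of


class StubRng:
    """Deterministic stand-in for a Generator in single-draw tests."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


def frogs_with_fitness(*fitnesses):
    return [Frog((i,), fit) for i, fit in enumerate(fitnesses)]


class TestSubmemplexProbability:
    def test_first_and_last_rank_values(self):
        assert submemplex_probability(1, 10) == pytest.approx(20 / 110)
        assert submemplex_probability(10, 10) == pytest.approx(2 / 110)

    @pytest.mark.parametrize("n", [2, 5, 10, 33])
    def test_distribution_sums_to_one(self, n):
        total = sum(submemplex_probability(j, n) for j in range(1, n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            submemplex_probability(0, 10)
        with pytest.raises(ValueError):
            submemplex_probability(11, 10)


class TestPartitionMemplexes:
    def test_round_robin_deal_by_rank(self):
        config = SFLAConfig(sfla_p=4, sfla_m=2, sfla_n=2, sfla_q=2)
        population = frogs_with_fitness(0.4, 0.3, 0.2, 0.1)
        memplexes = partition_memplexes(population, config)
        assert [f.fitness for f in memplexes[0]] == [0.4, 0.2]
        assert [f.fitness for f in memplexes[1]] == [0.3, 0.1]

    def test_single_memplex_is_sorted_population(self):
        config = SFLAConfig(sfla_p=3, sfla_m=1, sfla_n=3, sfla_q=2)
        population = frogs_with_fitness(0.1, 0.9, 0.5)
        (memplex,) = partition_memplexes(population, config)
        assert [f.fitness for f in memplex] == [0.9, 0.5, 0.1]

    def test_sizes_conserved(self):
        config = SFLAConfig(sfla_p=100, sfla_m=10, sfla_n=10, sfla_q=4)
        population = frogs_with_fitness(*np.linspace(0, 1, 100))
        memplexes = partition_memplexes(population, config)
        assert len(memplexes) == 10
        assert all(len(m) == 10 for m in memplexes)

    def test_unevaluated_frog_rejected(self):
        config = SFLAConfig(sfla_p=2, sfla_m=1, sfla_n=2, sfla_q=1)
        with pytest.raises(RuntimeError):
            partition_memplexes([Frog((0,), 0.5), Frog((1,), None)], config)


class TestSampleSubmemplex:
    def test_exhaustive_draw_returns_whole_memplex(self):
        memplex = sort_by_fitness(frogs_with_fitness(0.3, 0.9, 0.5))
        sample = sample_submemplex(memplex, 3, np.random.default_rng(0))
        assert [f.fitness for f in sample] == [0.9, 0.5, 0.3]

    def test_fixed_seed_identical(self):
        memplex = sort_by_fitness(frogs_with_fitness(*np.linspace(0.9, 0.1, 8)))
        a = sample_submemplex(memplex, 3, np.random.default_rng(4))
        b = sample_submemplex(memplex, 3, np.random.default_rng(4))
        assert [f.features for f in a] == [f.features for f in b]

    def test_sample_sorted_by_fitness(self):
        memplex = sort_by_fitness(frogs_with_fitness(*np.linspace(0.9, 0.1, 8)))
        sample = sample_submemplex(memplex, 4, np.random.default_rng(1))
        fits = [f.fitness for f in sample]
        assert fits == sorted(fits, reverse=True)


class TestLeapSize:
    def test_positive_step_capped(self):
        assert leap_size(10, 4, 5, StubRng(1.0)) == 5

    def test_equal_sizes_give_zero(self):
        for r in (0.0, 0.3, 0.99):
            assert leap_size(6, 6, 5, StubRng(r)) == 0

    def test_negative_step_capped(self):
        assert leap_size(4, 10, 5, StubRng(1.0)) == -5

    def test_truncation_toward_zero(self):
        assert leap_size(10, 4, 5, StubRng(0.6)) == 3  # int(3.6)
        assert leap_size(4, 10, 5, StubRng(0.6)) == -3  # int(-3.6)

    def test_bounds_over_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(2000):
            sp_b = int(rng.integers(1, 40))
            sp_w = int(rng.integers(1, 40))
            s = leap_size(sp_b, sp_w, 5, rng)
            assert abs(s) <= 5
            assert s * (sp_b - sp_w) >= 0  # sign follows the size difference


class TestLeapFeatures:
    def weights(self, p=6):
        return FeatureWeights(relief=np.linspace(1, 0.1, p), su=np.linspace(1, 0.1, p))

    def test_nothing_to_add_leaves_frog_unchanged(self):
        worst = Frog((0, 1), 0.4)
        better = Frog((0, 1), 0.9)
        out = leap_features(worst, better, 3, self.weights(), np.random.default_rng(0))
        assert out.features == worst.features
        assert out.fitness == 0.4  # unchanged frog keeps its cached fitness

    def test_removal_never_empties_frog(self):
        worst = Frog((2,), 0.4)
        out = leap_features(worst, Frog((0,), 0.9), -3, self.weights(), np.random.default_rng(0))
        assert out.features == (2,)

    def test_forced_draw_adds_all_candidates(self):
        worst = Frog((0,), 0.4)
        better = Frog((0, 1, 2), 0.9)
        out = leap_features(worst, better, 2, self.weights(), np.random.default_rng(0))
        assert set(out.features) == {0, 1, 2}
        assert out.fitness is None  # changed frog loses its cached fitness

    def test_zero_step_copies(self):
        worst = Frog((3, 4), 0.4)
        out = leap_features(worst, Frog((0,), 0.9), 0, self.weights(), np.random.default_rng(0))
        assert out.features == worst.features
        assert out.fitness == 0.4


class StubContext:
    """SearchContext stand-in with scripted refinement results."""

    def __init__(self, refine_results, random_result=None):
        self.config = SFLAConfig(sfla_p=4, sfla_m=2, sfla_n=2, sfla_q=2, s_max=3)
        p = 10
        self.weights = FeatureWeights(relief=np.linspace(1, 0.1, p), su=np.linspace(1, 0.1, p))
        self.rng_leap = np.random.default_rng(0)
        self._refine_results = list(refine_results)
        self._random_result = random_result
        self.refine_calls = 0
        self.random_calls = 0

    def refine(self, features):
        self.refine_calls += 1
        return self._refine_results.pop(0)

    def random_frog(self):
        self.random_calls += 1
        return self._random_result


class TestImproveWorstFrog:
    def test_stage_one_improvement_short_circuits(self):
        worst = Frog((5, 6), 0.4)
        ctx = StubContext([Frog((0, 1), 0.7)])
        out = improve_worst_frog(worst, Frog((0, 1, 2), 0.9), Frog((0,), 0.95), ctx)
        assert out.fitness == 0.7
        assert ctx.refine_calls == 1
        assert ctx.random_calls == 0

    def test_all_stages_fail_returns_original(self):
        worst = Frog((5, 6), 0.4)
        ctx = StubContext(
            [Frog((0,), 0.4), Frog((1,), 0.3)], random_result=Frog((2,), 0.4)
        )
        out = improve_worst_frog(worst, Frog((0, 1), 0.9), Frog((0,), 0.95), ctx)
        assert out is worst
        assert out.fitness == 0.4
        assert ctx.random_calls == 1

    def test_degenerate_guide_equal_to_worst_proceeds_to_stage_two(self):
        worst = Frog((5, 6), 0.4)
        ctx = StubContext([Frog((5, 6), 0.4), Frog((0, 5), 0.8)])
        out = improve_worst_frog(worst, worst, Frog((0,), 0.95), ctx)
        assert out.fitness == 0.8
        assert ctx.refine_calls == 2


class TestWorstOf:
    def test_lowest_fitness_wins_ties_by_larger_subset(self):
        frogs = [Frog((0,), 0.2), Frog((1, 2, 3), 0.2), Frog((4,), 0.9)]
        assert worst_of(frogs) is frogs[1]


@pytest.fixture()
def micro_config():
    return SFLAConfig(
        sfla_p=6,
        sfla_m=2,
        sfla_n=3,
        sfla_q=2,
        it_max=2,
        it_mem=2,
        s_max=3,
        inner_cv_folds=2,
        init_frac_range=(0.02, 0.1),
        seed=5,
    )


class TestRun:
    def test_zero_iterations_returns_best_initial_frog(self, small_fixture, micro_config):
        data, _ = small_fixture
        config = micro_config.with_seed(5)
        from dataclasses import replace

        result = run(data, replace(config, it_max=0))
        assert result.trace == []
        assert result.best_frog.fitness is not None

    def test_full_determinism(self, small_fixture, micro_config):
        data, _ = small_fixture
        a = run(data, micro_config)
        b = run(data, micro_config)
        assert a.to_dict() == b.to_dict()

    def test_trace_best_fitness_monotone(self, small_fixture, micro_config):
        data, _ = small_fixture
        result = run(data, micro_config)
        best = [t.best_fitness for t in result.trace]
        assert len(best) == micro_config.it_max
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_invalid_config_rejected_before_compute(self, small_fixture):
        data, _ = small_fixture
        with pytest.raises(ValueError):
            run(data, SFLAConfig(sfla_p=7, sfla_m=2, sfla_n=3))

    def test_eval_budget_truncates(self, small_fixture, micro_config):
        from dataclasses import replace

        data, _ = small_fixture
        result = run(data, replace(micro_config, max_evals=30))
        assert result.truncated
        assert result.best_frog.fitness is not None
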