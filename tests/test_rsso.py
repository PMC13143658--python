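"""Spider-swarm feature selection: colony rules, weights, recursive elimination."""

import itertools

import numpy as np
import pytest

from cardiofuse.errors import ConfigurationError, InvalidInputError, StateError
from cardiofuse.rsso import (
    compute_feature_weights,
    evaluate_fitness,
    init_population,
    recursive_feature_elimination,
    run_rsso,
    spider_step,
    spider_weights,
)
from cardiofuse.synthetic import PlantedTableSpec, generate_feature_table


def planted(n=300, d=20, k=4, effect=1.5, seed=0):
    frame, informative = generate_feature_table(
        PlantedTableSpec(n=n, d=d, k=k, effect=effect, seed=seed)
    )
    cols = [f"f{i}" for i in range(d)]
    return frame[cols].to_numpy(), frame["label"].to_numpy(), informative


class TestInitPopulation:
    @pytest.mark.parametrize("seed", range(25))
    def test_female_count_within_colony_bounds(self, seed):
        pop = init_population(d=5, n_spiders=20, rng=seed)
        n_f = int(pop.female.sum())
        assert 13 <= n_f <= 18  # floor(0.65*20) .. floor(0.9*20)

    def test_female_fraction_mean(self):
        fracs = [
            init_population(d=3, n_spiders=100, rng=s).female.mean() for s in range(1000)
        ]
        assert 0.70 <= np.mean(fracs) <= 0.85  # E[0.9 - 0.25 U] = 0.775

    def test_one_dimensional_positions(self):
        pop = init_population(d=1, n_spiders=6, rng=0)
        assert pop.positions.shape == (6, 1)
        assert (pop.positions >= 0).all() and (pop.positions <= 1).all()

    def test_tiny_population_rejected(self):
        with pytest.raises(ConfigurationError):
            init_population(d=3, n_spiders=3, rng=0)


class TestFitness:
    def test_empty_mask_scores_zero(self):
        X, y, _ = planted(n=50, d=4, k=2)
        assert evaluate_fitness(np.zeros(4), X, y) == 0.0

    def test_informative_mask_beats_noise_mask(self):
        X, y, informative = planted(n=200, d=10, k=2, effect=3.0, seed=1)
        good = np.zeros(10)
        good[informative] = 1.0
        noise = np.zeros(10)
        noise[[i for i in range(10) if i not in informative][:2]] = 1.0
        assert evaluate_fitness(good, X, y) > 0.9
        assert evaluate_fitness(good, X, y) > evaluate_fitness(noise, X, y)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((20, 3))
        with pytest.raises(InvalidInputError):
            evaluate_fitness(np.ones(3), X, np.zeros(20))


class TestSpiderStep:
    def test_weight_normalization(self):
        assert spider_weights([2, 4, 8]) == pytest.approx([0.0, 1 / 3, 1.0])

    def test_degenerate_fitness_gives_drift_only(self):
        pop = init_population(d=4, n_spiders=8, rng=1)
        pop.fitness = np.full(8, 0.5)
        moved = spider_step(pop, rng=2)
        assert np.allclose(moved.weights, 1.0)
        # pure drift: every coordinate moves by at most delta * 1/2 < 0.5
        assert np.max(np.abs(moved.positions - pop.positions)) <= 0.5

    def test_requires_evaluated_fitness(self):
        pop = init_population(d=4, n_spiders=8, rng=1)
        with pytest.raises(StateError):
            spider_step(pop, rng=0)

    def test_positions_stay_in_unit_cube(self):
        pop = init_population(d=3, n_spiders=10, rng=3)
        rng = np.random.default_rng(4)
        for it in range(5):
            pop.fitness = rng.random(10)
            pop = spider_step(pop, rng)
            assert (pop.positions >= 0).all() and (pop.positions <= 1).all()

    def test_best_fitness_monotone_over_iterations(self):
        X, y, _ = planted(n=120, d=6, k=2, effect=2.0, seed=2)
        result = run_rsso(X, y, n_spiders=8, n_iterations=12, seed=3)
        trace = result.fitness_trace
        assert all(a <= b + 1e-12 for a, b in zip(trace, trace[1:]))


class TestFeatureWeights:
    def test_magnitude_share(self):
        X = np.array([[3.0, 1.0], [-3.0, -1.0], [3.0, 1.0]])
        w = compute_feature_weights(X)
        assert w.wei == pytest.approx([0.75, 0.25])

    def test_weights_sum_to_one(self, rng):
        X = rng.normal(size=(50, 7)) * rng.uniform(0.1, 5, size=7)
        assert compute_feature_weights(X).wei.sum() == pytest.approx(1.0)

    def test_constant_feature_has_full_value_weight(self):
        X = np.column_stack([np.full(30, 2.0), np.random.default_rng(0).random(30)])
        w = compute_feature_weights(X)
        assert w.w_val[0] == pytest.approx(1.0)

    def test_zero_column_warns(self):
        X = np.column_stack([np.zeros(20), np.ones(20)])
        with pytest.warns(UserWarning):
            w = compute_feature_weights(X)
        assert w.wei[0] == 0.0

    def test_rank_in_unit_interval(self, rng):
        X = rng.normal(size=(40, 5))
        r = compute_feature_weights(X, inclusion_freq=rng.random(5)).rank
        assert (r >= 0).all() and (r <= 1).all()


class TestRecursiveElimination:
    def test_noise_only_dataset_hits_floor(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 8))
        y = rng.integers(0, 2, size=100)
        res = recursive_feature_elimination(X, y, compute_feature_weights(X), min_features=2)
        assert len(res.selected) == 2

    def test_trace_bookkeeping_is_consistent(self):
        X, y, _ = planted(n=150, d=8, k=2, effect=2.0, seed=5)
        res = recursive_feature_elimination(X, y, compute_feature_weights(X))
        for step in res.elimination_trace:
            assert step["removed"] == (step["c2"] >= step["c1"] - 0.005)

    def test_single_feature_returned_trivially(self):
        X, y, _ = planted(n=60, d=1, k=1, effect=2.0)
        res = recursive_feature_elimination(X, y, compute_feature_weights(X))
        assert res.selected == [0]


class TestRunRSSO:
    def test_same_seed_reproduces_result(self):
        X, y, _ = planted(n=120, d=8, k=2, effect=2.0, seed=9)
        a = run_rsso(X, y, n_spiders=6, n_iterations=5, seed=11)
        b = run_rsso(X, y, n_spiders=6, n_iterations=5, seed=11)
        assert a.selected == b.selected
        assert a.fitness_trace == b.fitness_trace
        assert a.rank_scores == b.rank_scores

    def test_two_informative_features_both_kept(self):
        X, y, _ = planted(n=150, d=2, k=2, effect=2.0, seed=13)
        res = run_rsso(X, y, n_spiders=6, n_iterations=5, seed=13)
        assert res.selected == [0, 1]

    def test_selected_subset_near_exhaustive_best(self):
        """For d <= 4 the selected mask's fitness is within tol of the best
        over all 2^d - 1 non-empty masks (brute-force oracle)."""
        X, y, _ = planted(n=200, d=4, k=2, effect=2.0, seed=17)
        res = run_rsso(X, y, n_spiders=6, n_iterations=8, seed=17)
        cv_seed = 17 % (2**31)
        best = max(
            evaluate_fitness(np.array(mask, dtype=float), X, y, cv_seed=cv_seed)
            for mask in itertools.product([0, 1], repeat=4)
            if any(mask)
        )
        chosen = np.zeros(4)
        chosen[res.selected] = 1.0
        assert evaluate_fitness(chosen, X, y, cv_seed=cv_seed) >= best - 0.005

    def test_selection_result_json_round_trip(self, tmp_path):
        X, y, _ = planted(n=100, d=5, k=2, effect=2.0, seed=19)
        res = run_rsso(X, y, n_spiders=6, n_iterations=4, seed=19)
        path = tmp_path / "selection.json"
        res.to_json(path)
        from cardiofuse.rsso import FeatureSelectionResult

        back = FeatureSelectionResult.from_json(path)
        assert back.selected == res.selected
        assert back.seed == res.seed
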