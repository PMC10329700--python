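"""Evolutionary engine: fitness, operators, evolution loop, exhaustive oracle."""

import numpy as np
import pytest

from evohdtree import EAConfig, evolve, exhaustive_best_tree, fitness
from evohdtree.core import (
    CROSSOVER_OPERATORS,
    MUTATION_OPERATORS,
    OPERATOR_CATALOGUE,
    crossover,
    initialize_population,
    mutate,
    training_f1,
)
from evohdtree.io import LabeledDataset
from evohdtree.node_tests import BivariateTest, UnivariateTest
from evohdtree.simulate import make_rank_pair_dataset, make_threshold_dataset
from evohdtree.tree import HeterogeneousTree, internal, leaf, refit_leaves


def _xor_dataset():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 1, 1, 0])
    return LabeledDataset(X, y, ["A", "B"])


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"crossover_prob": 1.5},
            {"mutation_prob": -0.1},
            {"alpha": -1.0},
            {"max_depth": 0},
            {"elitism": 100},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EAConfig(**kwargs).validate()

    def test_init_range_clamped_to_max_depth(self):
        cfg = EAConfig(max_depth=1)
        assert cfg.init_depth_range == (1, 1)
        cfg.validate()


class TestFitness:
    def test_formula(self):
        d = make_threshold_dataset(seed=0)
        t = HeterogeneousTree(
            internal(UnivariateTest(0, 5.0), leaf(), leaf()), d.metabolite_names
        )
        refit_leaves(t, d)
        assert training_f1(t) == pytest.approx(1.0)
        assert fitness(t, d, alpha=0.01) == pytest.approx(1.0 - 0.01)
        assert fitness(t, d, alpha=0.25) == pytest.approx(0.75)

    def test_f1_zero_when_no_positive_predictions(self):
        d = make_threshold_dataset(seed=0)
        t = HeterogeneousTree(leaf(label=0), d.metabolite_names)
        refit_leaves(t, d)
        t.root.label = 0  # force all-negative predictions
        assert training_f1(t) == 0.0


class TestOperators:
    def test_catalogue_is_more_than_a_dozen(self):
        assert len(OPERATOR_CATALOGUE) >= 13
        assert set(CROSSOVER_OPERATORS) <= set(OPERATOR_CATALOGUE)
        assert len(MUTATION_OPERATORS) + len(CROSSOVER_OPERATORS) == len(OPERATOR_CATALOGUE)

    def test_mutation_respects_depth_and_refits(self):
        d = make_rank_pair_dataset(seed=4)
        cfg = EAConfig(max_depth=2, population_size=4, seed=4)
        rng = np.random.default_rng(4)
        pop = initialize_population(d, cfg, rng)
        t = pop[0]
        for _ in range(200):
            t = mutate(t, d, rng, cfg)
            assert t.depth() <= 2
            assert sum(sum(lf.class_counts) for lf in t.leaves()) == d.n_samples

    def test_mutation_returns_new_tree(self):
        d = make_rank_pair_dataset(seed=5)
        rng = np.random.default_rng(5)
        t = initialize_population(d, EAConfig(population_size=2, seed=5), rng)[0]
        out = mutate(t, d, rng, EAConfig())
        assert out is not t

    def test_crossover_respects_depth(self):
        d = make_rank_pair_dataset(seed=6)
        cfg = EAConfig(population_size=6, max_depth=3, seed=6)
        rng = np.random.default_rng(6)
        pop = initialize_population(d, cfg, rng)
        for _ in range(50):
            a, b = crossover(pop[0], pop[1], d, rng, max_depth=3)
            assert a.depth() <= 3 and b.depth() <= 3


class TestInitialization:
    def test_population_size_and_depth_range(self):
        d = make_threshold_dataset(seed=1)
        cfg = EAConfig(population_size=20, init_depth_range=(1, 3), seed=1)
        pop = initialize_population(d, cfg, np.random.default_rng(1))
        assert len(pop) == 20
        assert all(1 <= t.depth() <= 3 for t in pop)
        # every tree arrives refit on the data
        assert all(t.fitted_on == d.fingerprint() for t in pop)


class TestEvolve:
    def test_best_fitness_monotone_with_elitism(self, quick_config):
        d = make_rank_pair_dataset(seed=9)
        _, log = evolve(d, quick_config, return_log=True)
        b = log.best_fitness
        assert all(b[i + 1] >= b[i] for i in range(len(b) - 1))

    def test_deterministic_given_seed(self, quick_config):
        d = make_rank_pair_dataset(seed=10)
        t1 = evolve(d, quick_config)
        t2 = evolve(d, quick_config)
        assert t1.to_json() == t2.to_json()

    def test_recovers_planted_rank_pair(self):
        d = make_rank_pair_dataset(seed=12)
        cfg = EAConfig(population_size=30, generations=25, stagnation_limit=10,
                       max_depth=2, seed=12)
        t = evolve(d, cfg)
        assert fitness(t, d, cfg.alpha) >= 0.9

    def test_stagnation_stops_early(self):
        d = make_threshold_dataset(seed=13)
        cfg = EAConfig(population_size=20, generations=500, stagnation_limit=3, seed=13)
        _, log = evolve(d, cfg, return_log=True)
        assert log.stopped_early
        assert log.generations_run < 500

    def test_log_tsv_format(self, quick_config):
        d = make_threshold_dataset(seed=14)
        _, log = evolve(d, quick_config, return_log=True)
        lines = log.to_tsv().strip().split("\n")
        assert lines[0] == "generation\tbest_fitness\tmean_fitness"
        assert len(lines) == log.generations_run + 1


class TestExhaustiveOracle:
    def test_xor_depth1_cannot_separate(self):
        d = _xor_dataset()
        t = exhaustive_best_tree(d, max_depth=1, alpha=0.01)
        assert fitness(t, d, 0.01) < 1 - 0.01

    def test_xor_depth2_perfect_with_two_nodes(self):
        d = _xor_dataset()
        t = exhaustive_best_tree(d, max_depth=2, alpha=0.01)
        assert training_f1(t) == pytest.approx(1.0)
        assert t.n_internal_nodes() == 2
        assert fitness(t, d, 0.01) == pytest.approx(1 - 2 * 0.01)

    def test_large_alpha_prefers_single_leaf(self):
        d = _xor_dataset()
        t = exhaustive_best_tree(d, max_depth=2, alpha=0.5)
        assert t.n_internal_nodes() == 0

    def test_tie_break_prefers_fewer_nodes(self):
        d = make_threshold_dataset(n_pos=8, n_neg=8, p=2, seed=2)
        t = exhaustive_best_tree(d, max_depth=2, alpha=0.01)
        assert training_f1(t) == pytest.approx(1.0)
        assert t.n_internal_nodes() == 1  # depth-1 rule suffices

    def test_deterministic(self):
        d = make_rank_pair_dataset(n_pos=6, n_neg=6, p=3, seed=3)
        assert (
            exhaustive_best_tree(d, 2).to_json() == exhaustive_best_tree(d, 2).to_json()
        )

    def test_too_large_instance_rejected(self):
        rng = np.random.default_rng(0)
        d = LabeledDataset(
            rng.normal(size=(40, 40)),
            rng.permutation([0, 1] * 20),
            [f"M{i}" for i in range(40)],
        )
        with pytest.raises(ValueError, match="too large"):
            exhaustive_best_tree(d, max_depth=2)

    def test_depth_guard(self):
        d = _xor_dataset()
        with pytest.raises(ValueError, match="max_depth"):
            exhaustive_best_tree(d, max_depth=3)
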