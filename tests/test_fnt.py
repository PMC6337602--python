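import json
import math

import numpy as np
import pytest

from laipt.fnt import (
    FNTModel,
    FNTNode,
    TrainConfig,
    eval_tree,
    evolve_structure,
    fitness_function,
    init_population,
    optimize_parameters,
    predict,
    random_tree,
    train_fnt,
    tree_depth,
)
from laipt.metrics import roc_auc


def leaf(i: int) -> FNTNode:
    return FNTNode(kind="leaf", feature_index=i)


def node(children, weights, m=0.0, n_act=1.0) -> FNTNode:
    return FNTNode(kind="function", children=children, weights=np.asarray(weights, float),
                   m=m, n_act=n_act)


def reference_eval(t: FNTNode, x: list[float]) -> float:
    """Independent scalar recursive evaluator (pure python math)."""
    if t.kind == "leaf":
        return x[t.feature_index]
    net = sum(w * reference_eval(c, x) for w, c in zip(t.weights, t.children))
    width = t.n_act if abs(t.n_act) >= 1e-6 else 1e-6
    return math.exp(-min(((net - t.m) / width) ** 2, 700.0))


class TestEvalTree:
    def test_zero_deviation_gives_one(self):
        t = node([leaf(0), leaf(1)], [1.0, 1.0], m=1.0, n_act=1.0)
        assert eval_tree(t, np.array([0.5, 0.5])) == 1.0

    def test_closed_form_gaussian(self):
        t = node([leaf(0), leaf(1)], [1.0, 0.0], m=0.0, n_act=1.0)
        assert eval_tree(t, np.array([1.0, 123.0])) == pytest.approx(math.exp(-1))

    def test_matches_reference_evaluator_on_random_trees(self):
        rng = np.random.default_rng(0)
        config = TrainConfig(max_depth=4)
        for _ in range(100):
            t = random_tree(config, feature_dim=6, rng=rng)
            x = rng.normal(size=6)
            assert eval_tree(t, x) == pytest.approx(reference_eval(t, x.tolist()), rel=1e-12)

    def test_root_output_in_unit_interval(self):
        rng = np.random.default_rng(1)
        config = TrainConfig(max_depth=3)
        X = rng.normal(scale=5, size=(50, 4))
        for _ in range(50):
            out = eval_tree(random_tree(config, 4, rng), X)
            assert np.all(out > 0) and np.all(out <= 1)

    def test_batch_equals_per_sample(self):
        rng = np.random.default_rng(2)
        t = random_tree(TrainConfig(), 5, rng)
        X = rng.normal(size=(20, 5))
        batch = eval_tree(t, X)
        assert batch == pytest.approx([eval_tree(t, row) for row in X])

    def test_nonfinite_input_rejected(self):
        t = node([leaf(0), leaf(1)], [1.0, 1.0])
        with pytest.raises(ValueError):
            eval_tree(t, np.array([np.nan, 1.0]))

    def test_out_of_range_leaf_named(self):
        t = node([leaf(0), leaf(7)], [1.0, 1.0])
        with pytest.raises(IndexError, match="root.1"):
            eval_tree(t, np.zeros(3))


class TestPopulation:
    def test_size_and_validity(self):
        rng = np.random.default_rng(3)
        pop = init_population(TrainConfig(population_size=10), 8, rng)
        assert len(pop) == 10
        for t in pop:
            assert t.kind == "function"
            assert tree_depth(t) <= TrainConfig().max_depth

    def test_seed_determinism(self):
        config = TrainConfig(population_size=6)
        a = init_population(config, 5, np.random.default_rng(9))
        b = init_population(config, 5, np.random.default_rng(9))
        assert [t.to_dict() for t in a] == [t.to_dict() for t in b]

    def test_depth_cap_over_many_samples(self):
        rng = np.random.default_rng(4)
        config = TrainConfig(max_depth=3, function_arities=(2, 3))
        for _ in range(1000):
            t = random_tree(config, 4, rng)
            assert 1 <= tree_depth(t) <= 3
            for f in _functions(t):
                assert len(f.children) in (2, 3)

    def test_bad_feature_dim_rejected(self):
        with pytest.raises(ValueError):
            init_population(TrainConfig(), 0, np.random.default_rng(0))


def _functions(t: FNTNode):
    if t.kind == "leaf":
        return []
    return [t] + [f for c in t.children for f in _functions(c)]


class TestEvolution:
    def test_no_crossover_yields_mutants_or_copies(self):
        rng = np.random.default_rng(5)
        config = TrainConfig(population_size=2, crossover_rate=0.0, mutation_rate=1.0)
        pop = init_population(config, 4, rng)
        out = evolve_structure(pop, lambda t: 0.0, config, rng, feature_dim=4)
        assert len(out) == 2

    def test_elitism_makes_best_fitness_non_increasing(self):
        rng = np.random.default_rng(6)
        data_rng = np.random.default_rng(7)
        X = data_rng.normal(size=(60, 5))
        y = (X[:, 0] > 0).astype(int)
        config = TrainConfig(population_size=12)
        pop = init_population(config, 5, rng)
        fit = lambda t: fitness_function(t, X, y, "rmse")
        best = min(fit(t) for t in pop)
        for _ in range(10):
            pop = evolve_structure(pop, fit, config, rng, feature_dim=5)
            new_best = min(fit(t) for t in pop)
            assert new_best <= best + 1e-12
            best = new_best

    def test_offspring_respect_invariants_across_generations(self):
        rng = np.random.default_rng(8)
        config = TrainConfig(population_size=8, max_depth=3)
        pop = init_population(config, 6, rng)
        X = rng.normal(size=(30, 6))
        y = rng.integers(2, size=30)
        fit = lambda t: fitness_function(t, X, y, "rmse")
        for _ in range(50):
            pop = evolve_structure(pop, fit, config, rng, feature_dim=6)
            for t in pop:
                assert tree_depth(t) <= 3
                for f in _functions(t):
                    assert len(f.weights) == len(f.children)
                    assert len(f.children) in config.function_arities


class TestParameterOptimization:
    def test_never_worse_than_input(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = (X[:, 1] > 0).astype(int)
        t = random_tree(TrainConfig(), 3, rng)
        before = fitness_function(t, X, y, "rmse")
        tuned = optimize_parameters(t, X, y, TrainConfig(), rng)
        assert fitness_function(tuned, X, y, "rmse") <= before + 1e-12

    def test_separable_1d_reaches_high_accuracy(self):
        rng = np.random.default_rng(10)
        x = np.r_[rng.normal(-2, 0.3, 50), rng.normal(2, 0.3, 50)][:, None]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        t = node([leaf(0), leaf(0)], [0.5, 0.5], m=0.0, n_act=1.0)
        tuned = optimize_parameters(t, x, y, TrainConfig(swarm_size=20, swarm_iters=40),
                                    np.random.default_rng(11))
        acc = np.mean((eval_tree(tuned, x) >= 0.5).astype(int) == y)
        assert acc >= 0.95

    def test_seed_determinism(self):
        rng_data = np.random.default_rng(12)
        X = rng_data.normal(size=(30, 3))
        y = rng_data.integers(2, size=30)
        while len(np.unique(y)) < 2:
            y = rng_data.integers(2, size=30)
        t = random_tree(TrainConfig(), 3, np.random.default_rng(1))
        a = optimize_parameters(t, X, y, TrainConfig(), np.random.default_rng(5))
        b = optimize_parameters(t, X, y, TrainConfig(), np.random.default_rng(5))
        assert a.to_dict() == b.to_dict()

    def test_single_class_rejected(self):
        t = node([leaf(0), leaf(0)], [1.0, 1.0])
        with pytest.raises(ValueError):
            optimize_parameters(t, np.zeros((5, 1)), np.ones(5), TrainConfig(),
                                np.random.default_rng(0))


class TestTraining:
    def test_separated_gaussian_clusters(self):
        rng = np.random.default_rng(13)
        X = np.r_[rng.normal(0, 1, (60, 4)), rng.normal(10, 1, (60, 4))]
        y = np.r_[np.zeros(60), np.ones(60)].astype(int)
        model = train_fnt(X, y, TrainConfig(seed=2, generations=4, population_size=16))
        _, labels = predict(model, X)
        assert np.mean(labels == y) >= 0.95

    def test_label_shuffle_gives_chance_auc(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(500, 6))
        y = np.array([0, 1] * 250)
        model = train_fnt(X, y, TrainConfig(seed=3, generations=3, population_size=12))
        scores, _ = predict(model, X)
        auc = roc_auc(scores, y).auc
        assert 0.35 <= auc <= 0.65

    def test_byte_identical_models_from_same_seed(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        cfg = TrainConfig(seed=4, generations=2, population_size=8, swarm_iters=5)
        a = train_fnt(X, y, cfg).to_json()
        b = train_fnt(X, y, cfg).to_json()
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_fnt(np.zeros((10, 2)), np.zeros(10), TrainConfig())


class TestPredict:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(16)
        X = np.r_[rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (30, 3))]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        return train_fnt(X, y, TrainConfig(seed=5, generations=2, population_size=8))

    def test_score_at_threshold_is_positive(self, model):
        x = np.random.default_rng(17).normal(size=3)
        score, _ = predict(model, x)
        boundary = FNTModel(root=model.root, feature_dim=3, threshold=float(score))
        _, label = predict(boundary, x)
        assert label == 1

    def test_batch_order_invariance(self, model):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(15, 3))
        perm = rng.permutation(15)
        scores, _ = predict(model, X)
        scores_perm, _ = predict(model, X[perm])
        assert scores_perm == pytest.approx(scores[perm])

    def test_batch_equals_loop(self, model):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(10, 3))
        scores, labels = predict(model, X)
        singles = [predict(model, row) for row in X]
        assert scores == pytest.approx([s for s, _ in singles])
        assert labels.tolist() == [l for _, l in singles]

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((4, 7)))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(20, 4))
        y = np.array([0, 1] * 10)
        model = train_fnt(X, y, TrainConfig(seed=6, generations=2, population_size=8))
        clone = FNTModel.from_json(model.to_json())
        s1, _ = predict(model, X)
        s2, _ = predict(clone, X)
        assert s2 == pytest.approx(s1, rel=0, abs=0)
        assert clone.to_json() == model.to_json()

    def test_file_round_trip(self, tmp_path):
        t = node([leaf(0), node([leaf(1), leaf(0)], [0.3, -0.2], m=0.5, n_act=0.7)], [1.0, -1.0])
        model = FNTModel(root=t, feature_dim=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FNTModel.from_json(path)
        assert json.loads(back.to_json()) == json.loads(model.to_json())
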