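import numpy as np
import pytest

from fraccs import (
    BinaryMask,
    FeatureSelectionProblem,
    OptimizerConfig,
    WORST_FITNESS,
    binarize,
    fitness,
    generate_features,
    knn_error,
    select_features,
)
from fraccs.synthetic import SyntheticSpec


@pytest.fixture(scope="module")
def planted():
    return generate_features(
        SyntheticSpec(n_samples=120, n_features=10, n_informative=3,
                      effect_size=3.0, seed=11)
    )


class TestBinarize:
    def test_strict_threshold(self):
        mask = binarize(np.array([0.7, 0.2, 0.5]))
        assert mask.mask.tolist() == [1, 0, 0]

    def test_all_zero_vector(self):
        assert binarize(np.zeros(4)).count == 0

    def test_idempotent_on_binary_inputs(self, rng):
        m = binarize(rng.uniform(size=8))
        again = binarize(m.mask.astype(float))
        assert np.array_equal(m.mask, again.mask)

    def test_selected_indices_consistent(self):
        m = binarize(np.array([0.9, 0.1, 0.8]))
        assert m.selected_indices.tolist() == [0, 2]
        assert m.count == 2


class TestFitness:
    def test_direct_arithmetic(self):
        m = BinaryMask(np.array([1] * 50 + [0] * 50))
        assert fitness(m, 0.1, 100, 0.9) == pytest.approx(0.14)

    def test_pure_performance_weight(self):
        m = BinaryMask(np.array([1, 1, 0]))
        assert fitness(m, 0.37, 3, 1.0) == pytest.approx(0.37)

    def test_penalty_monotone_in_mask_size(self):
        vals = [
            fitness(BinaryMask(np.array([1] * k + [0] * (10 - k))), 0.2, 10, 0.9)
            for k in range(1, 11)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_empty_mask_is_worst(self):
        assert fitness(BinaryMask(np.zeros(5, dtype=int)), 0.0, 5, 0.9) == WORST_FITNESS

    def test_bounded_for_valid_inputs(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 10))
            m = BinaryMask(np.array([1] * k + [0] * (10 - k)))
            val = fitness(m, float(rng.uniform()), 10, float(rng.uniform()))
            assert 0.0 <= val <= 1.0

    def test_oversized_mask_raises(self):
        with pytest.raises(ValueError):
            fitness(BinaryMask(np.ones(5, dtype=int)), 0.1, 3, 0.9)


class TestKnnError:
    def test_separable_clusters_zero_error(self, rng):
        n = 80
        labels = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 4)) * 0.1
        x[labels == 1, :2] += 10.0
        err = knn_error(x, labels, BinaryMask(np.array([1, 1, 0, 0])), k=3, seed=0)
        assert err == 0.0

    def test_permuted_labels_near_majority_rate(self, rng):
        n = 400
        labels = np.repeat([0, 1], [240, 160])
        x = rng.normal(size=(n, 5))
        errs = [
            knn_error(x, np.random.default_rng(s).permutation(labels),
                      BinaryMask(np.ones(5, dtype=int)), k=7, seed=s)
            for s in range(5)
        ]
        # uninformative features: error close to minority rate 0.4
        assert np.mean(errs) == pytest.approx(0.4, abs=0.12)

    def test_empty_mask_raises(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.tile([0, 1], 10)
        with pytest.raises(ValueError):
            knn_error(x, y, BinaryMask(np.zeros(3, dtype=int)))

    def test_k_exceeding_training_size_raises(self, rng):
        x = rng.normal(size=(10, 2))
        y = np.tile([0, 1], 5)
        with pytest.raises(ValueError):
            knn_error(x, y, BinaryMask(np.ones(2, dtype=int)), k=50)


class TestProblem:
    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            FeatureSelectionProblem(rng.normal(size=(10, 3)), np.zeros(10))

    def test_outer_split_is_stratified_and_disjoint(self, planted):
        prob = FeatureSelectionProblem(planted.features, planted.labels, seed=0)
        x_tr, y_tr = prob.train_data
        x_te, y_te = prob.test_data
        assert len(y_tr) + len(y_te) == len(planted.labels)
        assert abs(y_tr.mean() - y_te.mean()) < 0.1

    def test_objective_matches_fitness_of_binarized_mask(self, planted):
        prob = FeatureSelectionProblem(planted.features, planted.labels, seed=0)
        obj = prob.make_objective()
        x = np.array([0.9, 0.1, 0.8, 0.2, 0.7, 0.3, 0.6, 0.4, 0.55, 0.45])
        m = binarize(x)
        eta = prob.validation_error(m)
        assert obj(x) == pytest.approx(fitness(m, eta, prob.dim, prob.fitness_weight))

    def test_empty_mask_objective_is_sentinel(self, planted):
        prob = FeatureSelectionProblem(planted.features, planted.labels, seed=0)
        assert prob.make_objective()(np.zeros(prob.dim)) == WORST_FITNESS


@pytest.fixture(scope="module")
def small_cfg():
    return OptimizerConfig(n_nests=10, n_cuckoos_per_iter=6, max_iter=25, seed=3)


class TestSelectFeatures:
    def test_deterministic_rerun(self, planted, small_cfg):
        prob = FeatureSelectionProblem(planted.features, planted.labels, seed=3)
        r1 = select_features(prob, small_cfg, method="cfo_cs")
        r2 = select_features(prob, small_cfg, method="cfo_cs")
        assert np.array_equal(r1.mask.mask, r2.mask.mask)
        assert r1.fitness == r2.fitness

    def test_reported_fitness_matches_recomputation(self, planted, small_cfg):
        prob = FeatureSelectionProblem(planted.features, planted.labels, seed=3)
        res = select_features(prob, small_cfg, method="cs")
        eta = prob.validation_error(res.mask)
        assert res.fitness == fitness(res.mask, eta, prob.dim, prob.fitness_weight)
        assert res.fitness == res.trace.best_fitness

    def test_trace_monotone(self, planted, small_cfg):
        prob = FeatureSelectionProblem(planted.features, planted.labels, seed=3)
        res = select_features(prob, small_cfg, method="cfo_cs")
        assert np.all(np.diff(res.trace.best_fitness_per_iter) <= 0)

    def test_pure_sparsity_weight_drives_to_single_feature(self, planted):
        prob = FeatureSelectionProblem(
            planted.features, planted.labels, fitness_weight=0.0, seed=1
        )
        cfg = OptimizerConfig(n_nests=10, n_cuckoos_per_iter=6, max_iter=60, seed=1)
        res = select_features(prob, cfg, method="cs")
        assert res.mask.count == 1

    def test_unknown_method_rejected(self, planted, small_cfg):
        prob = FeatureSelectionProblem(planted.features, planted.labels)
        with pytest.raises(ValueError):
            select_features(prob, small_cfg, method="annealing")

    def test_informative_columns_recovered_on_easy_problem(self, planted, small_cfg):
        prob = FeatureSelectionProblem(planted.features, planted.labels, seed=3)
        res = select_features(prob, small_cfg, method="cfo_cs")
        truth = set(planted.informative_indices.tolist())
        chosen = set(res.selected_indices.tolist())
        # effect size 3: selected set should hit planted columns above chance
        assert len(chosen & truth) / len(chosen) > 3 / 10
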