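import numpy as np
import pytest
from scipy import sparse
from sklearn.metrics import average_precision_score, roc_auc_score

from rbpgraph.kernel import KernelParams
from rbpgraph.learn import (ClassifierParams, LinearModel, RegressionParams, auroc,
                            average_precision, crossvalidate, line_search,
                            line_search_classifier, margin, relative_error_reduction,
                            train_classifier, train_regressor, tuning_subset)

KP = KernelParams(bits=8)
DIM = 256


def toy_matrix(rows):
    X = np.zeros((len(rows), DIM))
    for i, cols in enumerate(rows):
        for c in cols:
            X[i, c] += 1.0
    return sparse.csr_matrix(X)


def separable(n=20, seed=0):
    """Positives activate feature 1, negatives feature 2."""
    rng = np.random.default_rng(seed)
    rows, y = [], []
    for i in range(n):
        noise = [int(rng.integers(10, DIM))]
        if i % 2 == 0:
            rows.append([1] + noise)
            y.append(1)
        else:
            rows.append([2] + noise)
            y.append(-1)
    return toy_matrix(rows), np.array(y)


class TestClassifier:
    def test_separable_data_reaches_training_auroc_one(self):
        X, y = separable()
        m = train_classifier(X, y, ClassifierParams(epochs=20, seed=0), KP)
        assert auroc(m.margin(X), y) == 1.0

    def test_same_seed_identical_weights(self):
        X, y = separable()
        p = ClassifierParams(epochs=5, seed=3)
        m1 = train_classifier(X, y, p, KP)
        m2 = train_classifier(X, y, p, KP)
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias

    def test_single_class_rejected(self):
        X, _ = separable()
        with pytest.raises(ValueError):
            train_classifier(X, np.ones(X.shape[0]), ClassifierParams(), KP)

    def test_sgd_objective_nonincreasing_over_epochs(self):
        X, y = separable(n=40, seed=1)
        lam = 1e-3

        def objective(m):
            marg = y * m.margin(X)
            hinge = np.maximum(0.0, 1.0 - marg).mean()
            return hinge + 0.5 * lam * float(m.weights @ m.weights)

        objs = [objective(train_classifier(
            X, y, ClassifierParams(lambda_=lam, epochs=e, seed=0), KP))
            for e in (1, 5, 20, 60)]
        assert objs[-1] <= objs[0] + 1e-9
        assert objs[-1] <= min(objs[:2]) + 1e-6


class TestRegressor:
    def test_exact_linear_relationship_recovered(self):
        rng = np.random.default_rng(0)
        X = sparse.csr_matrix(rng.normal(size=(30, DIM)))
        w_true = np.zeros(DIM)
        w_true[:3] = [1.0, -2.0, 0.5]
        y = X @ w_true
        m = train_regressor(X, y, RegressionParams(c=100.0, epsilon=0.0), KP)
        assert np.allclose(m.margin(X), y, atol=1e-2)

    def test_constant_targets_rejected(self):
        X = sparse.csr_matrix(np.eye(5, DIM))
        with pytest.raises(ValueError):
            train_regressor(X, np.ones(5), RegressionParams(), KP)

    def test_epsilon_wider_than_range_admits_flat_model(self):
        rng = np.random.default_rng(0)
        X = sparse.csr_matrix(rng.normal(size=(20, DIM)))
        y = rng.uniform(0, 0.1, 20)
        m = train_regressor(X, y, RegressionParams(c=1.0, epsilon=1.0), KP)
        # a flat model inside the epsilon tube is optimal: near-zero weights
        assert float(np.abs(m.weights).sum()) < 1e-3


class TestMargin:
    def test_zero_vector_returns_bias(self):
        m = LinearModel("classification", np.zeros(DIM), 0.75, KP)
        assert margin(m, sparse.csr_matrix((1, DIM))) == pytest.approx(0.75)

    def test_margin_is_linear_in_the_vector(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=DIM)
        m = LinearModel("classification", w, 0.3, KP)
        x = sparse.csr_matrix(rng.normal(size=(1, DIM)))
        m1 = float(m.margin(x)[0]) - 0.3
        m2 = float(m.margin(2.5 * x)[0]) - 0.3
        assert m2 == pytest.approx(2.5 * m1)


class TestMetrics:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, -1, -1]) == 1.0

    def test_all_tied_margins_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_half_concordant_pairs(self):
        assert auroc([0.8, 0.7, 0.9, 0.1], [1, 1, -1, -1]) == 0.5

    def test_auroc_matches_sklearn_on_random_data(self, rng):
        for _ in range(20):
            y = rng.choice([-1, 1], 30)
            if len(set(y)) < 2:
                continue
            m = rng.normal(size=30).round(1)  # rounding forces ties
            assert auroc(m, y) == pytest.approx(roc_auc_score(y, m))

    def test_auroc_invariant_under_monotone_transform(self, rng):
        y = rng.choice([-1, 1], 40)
        m = rng.normal(size=40)
        assert auroc(m, y) == pytest.approx(auroc(np.exp(3 * m) + 7, y))

    def test_auroc_label_flip_symmetry_on_tie_free_data(self, rng):
        y = rng.choice([-1, 1], 40)
        m = rng.permutation(40).astype(float)  # distinct margins
        assert auroc(m, y) == pytest.approx(1.0 - auroc(m, -y))

    def test_average_precision_hand_example(self):
        # ranking [P, N, P] -> (1/1 + 2/3) / 2
        assert average_precision([0.9, 0.5, 0.1], [1, -1, 1]) == pytest.approx(5 / 6)

    def test_average_precision_all_positives_first(self):
        assert average_precision([3, 2, 1, 0], [1, 1, -1, -1]) == 1.0

    def test_average_precision_single_positive_rank_k(self):
        assert average_precision([4, 3, 2, 1], [-1, -1, 1, -1]) == pytest.approx(1 / 3)

    def test_average_precision_matches_sklearn(self, rng):
        for _ in range(10):
            y = rng.choice([-1, 1], 25)
            if not (y > 0).any():
                continue
            m = rng.normal(size=25)  # tie-free
            assert average_precision(m, y) == pytest.approx(
                average_precision_score((y > 0).astype(int), m))

    def test_relative_error_reduction(self):
        assert relative_error_reduction(0.5, 0.75) == pytest.approx(0.5)
        assert relative_error_reduction(0.3, 0.3) == 0.0
        assert relative_error_reduction(0.65, 0.86) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            relative_error_reduction(1.0, 1.0)


class TestCrossValidation:
    def test_separable_data_scores_one(self):
        X, y = separable(n=60)
        res = crossvalidate(X, y, ClassifierParams(epochs=10, seed=0), k=5, seed=0)
        assert res.mean_score == 1.0

    def test_label_permutation_scores_near_half(self):
        rng = np.random.default_rng(0)
        X, y = separable(n=100)
        y_perm = rng.permutation(y)
        res = crossvalidate(X, y_perm, ClassifierParams(epochs=5, seed=0), k=5, seed=0)
        assert 0.3 < res.mean_score < 0.7

    def test_fold_assignment_reproducible(self):
        X, y = separable(n=40)
        p = ClassifierParams(epochs=3, seed=1)
        a = crossvalidate(X, y, p, k=4, seed=9)
        b = crossvalidate(X, y, p, k=4, seed=9)
        assert a.fold_scores == b.fold_scores
        assert np.array_equal(a.margins, b.margins)

    def test_too_few_examples_per_class_rejected(self):
        X, y = separable(n=10)
        with pytest.raises(ValueError):
            crossvalidate(X, y, ClassifierParams(), k=10, seed=0)


class TestLineSearch:
    def test_single_parameter_grid_maximum_found(self):
        best, score = line_search(lambda cfg: -(cfg["x"] - 3) ** 2,
                                  {"x": [0, 1, 2, 3, 4, 5]})
        assert best["x"] == 3 and score == 0

    def test_round_robin_couples_parameters(self):
        f = lambda cfg: -(cfg["x"] - 2) ** 2 - (cfg["y"] + 1) ** 2
        best, _ = line_search(f, {"x": [0, 1, 2], "y": [-2, -1, 0]})
        assert best == {"x": 2, "y": -1}

    def test_tuning_subset_sizes(self):
        y = np.r_[np.ones(30000), -np.ones(20000)]
        assert tuning_subset(y, seed=0).size == 1000  # min(1000, 5000)
        y = np.r_[np.ones(400), -np.ones(400)]
        assert tuning_subset(y, seed=0).size == 80  # 10% branch

    def test_line_search_classifier_excludes_tuning_subset(self):
        X, y = separable(n=200)
        params, rest, score = line_search_classifier(
            X, y, {"lambda_": [1e-2, 1e-4], "epochs": [3, 6]}, seed=0, cv_k=3)
        assert rest.size == 180  # 10% held aside for tuning
        assert isinstance(params, ClassifierParams)
        assert score > 0.9


class TestPersistence:
    def test_save_load_margin_bit_identical(self, tmp_path, rng):
        w = rng.normal(size=DIM) * (rng.random(DIM) < 0.1)
        m = LinearModel("classification", w, -0.123456789, KP,
                        meta={"note": "roundtrip"})
        path = tmp_path / "model.json"
        m.save(path)
        back = LinearModel.load(path)
        assert np.array_equal(back.weights, m.weights)
        assert back.bias == m.bias
        assert back.kernel_params == m.kernel_params
        X = sparse.csr_matrix(rng.normal(size=(5, DIM)))
        assert np.array_equal(back.margin(X), m.margin(X))
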