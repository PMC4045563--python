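"""Polynomial-kernel SVM: kernel, training, prediction, LOOCV metrics."""

import numpy as np
import pytest

from mfractal import (
    ClassifierConfig,
    DegenerateTrainingError,
    InsufficientDataError,
    InvalidInputError,
    LabeledDataset,
    evaluate_loocv,
    polynomial_kernel,
    predict,
    train,
)
from mfractal.classify import _metrics, decision_value


def make_dataset(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    return LabeledDataset(
        features=X, labels=np.asarray(y), ids=tuple(str(i) for i in range(len(y)))
    )


@pytest.fixture
def separable_1d():
    return make_dataset([[-2.0], [-1.9], [2.0], [2.1]], [-1, -1, 1, 1])


@pytest.fixture
def xor_dataset(rng):
    # XOR pattern with small within-cluster jitter
    centers = np.array(
        [[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float
    ).repeat(5, axis=0)
    labels = np.array([1] * 10 + [-1] * 10)
    X = centers + 0.1 * rng.normal(size=centers.shape)
    return make_dataset(X, labels)


class TestPolynomialKernel:
    @pytest.mark.parametrize(
        "x,y,deg,expected",
        [
            ((0, 0), (0, 0), 4, 1.0),
            ((1, 1), (1, 1), 2, 9.0),
            ((1, 2, 3), (1, 0, 1), 1, 5.0),
        ],
    )
    def test_values(self, x, y, deg, expected):
        assert polynomial_kernel(np.array(x), np.array(y), deg) == expected

    def test_symmetry(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=(2, 6))
            assert polynomial_kernel(x, y, 3) == pytest.approx(
                polynomial_kernel(y, x, 3)
            )

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidInputError):
            polynomial_kernel(np.ones(3), np.ones(4), 2)


class TestTrain:
    def test_separable_clusters_fit_perfectly(self, separable_1d):
        model = train(separable_1d, ClassifierConfig(degree=1))
        preds = [predict(model, f) for f in separable_1d.features]
        np.testing.assert_array_equal(preds, separable_1d.labels)

    def test_xor_separable_at_degree_two(self, xor_dataset):
        model = train(xor_dataset, ClassifierConfig(degree=2, C=10.0))
        preds = [predict(model, f) for f in xor_dataset.features]
        np.testing.assert_array_equal(preds, xor_dataset.labels)

    @pytest.mark.parametrize("degree,C", [(1, 1.0), (2, 10.0), (4, 1.0)])
    def test_dual_constraints_hold(self, xor_dataset, degree, C):
        model = train(xor_dataset, ClassifierConfig(degree=degree, C=C))
        assert abs(np.sum(model.alphas * model.support_labels)) < 1e-6
        assert np.all(model.alphas >= 0)
        assert np.all(model.alphas <= C + 1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train(make_dataset([[1.0], [2.0]], [1, 1]))

    def test_decision_matches_sklearn_backend(self, xor_dataset):
        """In-package kernel expansion reproduces the solver's decision values."""
        from sklearn.svm import SVC

        cfg = ClassifierConfig(degree=3, C=2.0, standardize=False)
        model = train(xor_dataset, cfg)
        svc = SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=2.0)
        svc.fit(xor_dataset.features, xor_dataset.labels)
        for f in xor_dataset.features[:5]:
            assert decision_value(model, f) == pytest.approx(
                float(svc.decision_function(f[None, :])[0]), rel=1e-8, abs=1e-10
            )


class TestPredict:
    def test_margin_support_vectors_self_consistent(self, xor_dataset):
        cfg = ClassifierConfig(degree=2, C=10.0, standardize=False)
        model = train(xor_dataset, cfg)
        # support vectors with alpha < C sit on the margin: |g| = 1
        on_margin = model.alphas < cfg.C - 1e-6
        for sv, lab in zip(
            model.support_vectors[on_margin], model.support_labels[on_margin]
        ):
            assert predict(model, sv) == lab

    def test_permutation_invariance(self, xor_dataset, rng):
        model_a = train(xor_dataset, ClassifierConfig(degree=2))
        perm = rng.permutation(len(xor_dataset))
        shuffled = LabeledDataset(
            features=xor_dataset.features[perm],
            labels=xor_dataset.labels[perm],
            ids=tuple(np.array(xor_dataset.ids)[perm]),
        )
        model_b = train(shuffled, ClassifierConfig(degree=2))
        probe = rng.normal(size=(20, 2))
        preds_a = [predict(model_a, x) for x in probe]
        preds_b = [predict(model_b, x) for x in probe]
        assert preds_a == preds_b

    def test_duplicated_data_same_boundary(self, separable_1d, rng):
        doubled = LabeledDataset(
            features=np.vstack([separable_1d.features] * 2),
            labels=np.concatenate([separable_1d.labels] * 2),
            ids=tuple(f"s{i}" for i in range(8)),
        )
        m1 = train(separable_1d, ClassifierConfig(degree=1))
        m2 = train(doubled, ClassifierConfig(degree=1))
        probe = rng.uniform(-3, 3, size=(50, 1))
        assert [predict(m1, x) for x in probe] == [predict(m2, x) for x in probe]

    def test_dimension_mismatch(self, separable_1d):
        model = train(separable_1d, ClassifierConfig(degree=1))
        with pytest.raises(InvalidInputError):
            predict(model, np.ones(3))


class TestMetricsBookkeeping:
    def test_all_correct_but_one_positive(self):
        true = np.array([1] * 5 + [-1] * 4)
        pred = true.copy()
        pred[0] = -1  # one missed positive
        ccr, sens, spec, *_ = _metrics(true, pred)
        assert sens == pytest.approx(4 / 5)
        assert spec == 1.0
        assert ccr == pytest.approx(8 / 9)

    def test_identities_exact(self, rng):
        true = rng.choice([-1, 1], size=30)
        # ensure both classes appear
        true[:2] = [1, -1]
        pred = np.where(rng.random(30) < 0.8, true, -true)
        ccr, sens, spec, *_ = _metrics(true, pred)
        n_pos = int(np.sum(true == 1))
        assert ccr * 30 == pytest.approx(np.sum(true == pred))
        assert sens * n_pos == pytest.approx(np.sum((true == 1) & (pred == 1)))

    def test_order_invariance(self, rng):
        true = np.array([1] * 10 + [-1] * 10)
        pred = np.where(rng.random(20) < 0.7, true, -true)
        perm = rng.permutation(20)
        assert _metrics(true, pred) == _metrics(true[perm], pred[perm])


class TestLOOCV:
    def test_separable_dataset_perfect(self, rng):
        X = np.vstack(
            [rng.normal([3, 3], 0.2, (10, 2)), rng.normal([-3, -3], 0.2, (10, 2))]
        )
        ds = make_dataset(X, [1] * 10 + [-1] * 10)
        rep = evaluate_loocv(ds, ClassifierConfig(degree=4))
        assert (rep.ccr, rep.sensitivity, rep.specificity) == (1.0, 1.0, 1.0)
        assert rep.ccr_std == 0.0

    def test_report_consistent_with_per_fold_table(self, texture_report):
        correct = [t == p for _, t, p in texture_report.per_fold]
        assert texture_report.ccr == pytest.approx(np.mean(correct))
        pos = [t == p for _, t, p in texture_report.per_fold if t == 1]
        assert texture_report.sensitivity == pytest.approx(np.mean(pos))

    def test_too_few_per_class_rejected(self):
        ds = make_dataset([[0.0], [1.0], [2.0]], [1, -1, -1])
        with pytest.raises(InsufficientDataError):
            evaluate_loocv(ds)

    def test_fold_standardization_excludes_test_sample(self, rng):
        """Refitting on the fold's training split reproduces the stored loc/scale."""
        X = np.vstack(
            [rng.normal(2, 1, (5, 3)), rng.normal(-2, 1, (5, 3))]
        )
        ds = make_dataset(X, [1] * 5 + [-1] * 5)
        i = 3  # any held-out index
        mask = np.ones(10, dtype=bool)
        mask[i] = False
        fold = LabeledDataset(
            features=ds.features[mask],
            labels=ds.labels[mask],
            ids=tuple(np.array(ds.ids)[mask]),
        )
        model = train(fold, ClassifierConfig())
        np.testing.assert_allclose(model.loc, ds.features[mask].mean(axis=0))
        assert not np.allclose(model.loc, ds.features.mean(axis=0))
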