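import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dyadphys.behavior import LabeledDataset
from dyadphys.errors import DataError, FitError
from dyadphys.qda import (ConfusionMatrix, ScoreReport, fit_qda,
                          leave_one_sample_out, leave_one_subject_out,
                          macro_scores, predict_qda)
from tests.conftest import make_gaussian_dataset


class TestFitQda:
    def test_recovers_means(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        y = np.array([0] * 200 + [1] * 200)
        model = fit_qda(X[:, None], y)
        assert abs(model.means[0, 0] - 0.0) < 0.3
        assert abs(model.means[1, 0] - 10.0) < 0.3
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_duplicate_invariance(self, gaussian_dataset):
        X, y = gaussian_dataset
        m1 = fit_qda(X, y)
        m2 = fit_qda(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.means, m2.means, atol=1e-10)
        # duplicating changes ddof-1 covariance only by (2n-1)/(2n-2) vs n-1
        np.testing.assert_allclose(m1.covariances, m2.covariances, rtol=0.02)
        np.testing.assert_allclose(m1.priors, m2.priors)

    def test_small_class_raises(self):
        X = np.array([[0.0], [1.0], [5.0]])
        y = np.array([0, 0, 1])
        with pytest.raises(FitError, match="1"):
            fit_qda(X, y)

    def test_single_class_raises(self):
        with pytest.raises(FitError):
            fit_qda(np.zeros((4, 1)), np.zeros(4))


class TestPredictQda:
    def test_predicts_own_mean(self, gaussian_dataset):
        X, y = gaussian_dataset
        model = fit_qda(X, y)
        for i, c in enumerate(model.classes):
            assert predict_qda(model, model.means[i]) == c

    def test_midpoint_tie_breaks_low(self):
        rng = np.random.default_rng(1)
        # symmetric 1-D classes around +-1 with identical samples mirrored
        base = rng.normal(0, 0.5, 50)
        X = np.concatenate([base - 1.0, -base + 1.0])[:, None]
        y = np.array([0] * 50 + [1] * 50)
        model = fit_qda(X, y)
        assert predict_qda(model, np.array([0.0])) == 0

    def test_density_oracle_equivalence(self, gaussian_dataset):
        X, y = gaussian_dataset
        model = fit_qda(X, y)
        rng = np.random.default_rng(2)
        pts = rng.uniform(X.min(), X.max(), size=(100, X.shape[1]))
        preds = predict_qda(model, pts)
        for x, p in zip(pts, preds):
            scores = [np.log(model.priors[i])
                      + multivariate_normal.logpdf(x, model.means[i],
                                                   model.covariances[i])
                      for i in range(model.classes.size)]
            assert model.classes[int(np.argmax(scores))] == p

    def test_lda_limit(self, gaussian_dataset):
        """With tied covariances QDA decisions equal a hand-rolled LDA."""
        X, y = gaussian_dataset
        model = fit_qda(X, y)
        pooled = np.mean(model.covariances, axis=0)
        model.covariances = np.stack([pooled] * model.classes.size)
        from scipy.linalg import cholesky
        L = cholesky(pooled, lower=True)
        model.chol = [L] * model.classes.size
        model.log_dets = np.full(model.classes.size,
                                 2 * np.sum(np.log(np.diag(L))))
        rng = np.random.default_rng(3)
        pts = rng.uniform(X.min(), X.max(), size=(100, X.shape[1]))
        qda_preds = predict_qda(model, pts)
        # LDA oracle: linear discriminant w_c.x + b_c
        inv = np.linalg.inv(pooled)
        scores = np.stack([
            pts @ inv @ model.means[i]
            - 0.5 * model.means[i] @ inv @ model.means[i]
            + np.log(model.priors[i])
            for i in range(model.classes.size)], axis=1)
        lda_preds = model.classes[np.argmax(scores, axis=1)]
        np.testing.assert_array_equal(qda_preds, lda_preds)

    def test_dimension_mismatch(self, gaussian_dataset):
        X, y = gaussian_dataset
        model = fit_qda(X, y)
        with pytest.raises(DataError):
            predict_qda(model, np.zeros(X.shape[1] + 1))


class TestMacroScores:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(labels=np.array([1, 2, 3]),
                             counts=np.diag([5, 7, 9]))
        rep = macro_scores(cm)
        assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_hand_case(self):
        cm = ConfusionMatrix(labels=np.array([0, 1]),
                             counts=np.array([[5, 5], [0, 10]]))
        rep = macro_scores(cm)
        assert rep.recall == pytest.approx(0.75, abs=1e-12)
        assert rep.precision == pytest.approx((1.0 + 10 / 15) / 2, abs=1e-12)
        expected_f1 = 2.0 / (1.0 / 0.75 + 1.0 / ((1.0 + 10 / 15) / 2))
        assert rep.f1 == pytest.approx(expected_f1, abs=1e-12)

    def test_never_predicted_class_finite(self):
        cm = ConfusionMatrix(labels=np.array([0, 1, 2]),
                             counts=np.array([[4, 0, 0], [3, 0, 0],
                                              [0, 0, 0]]))
        rep = macro_scores(cm)
        assert 0.0 <= rep.f1 <= 1.0

    def test_empty_raises(self):
        cm = ConfusionMatrix.empty([0, 1])
        with pytest.raises(DataError):
            macro_scores(cm)

    def test_zero_scores_f1_zero(self):
        cm = ConfusionMatrix(labels=np.array([0, 1]),
                             counts=np.array([[0, 4], [3, 0]]))
        assert macro_scores(cm).f1 == 0.0


class TestLeaveOneSampleOut:
    def test_separable_clusters(self):
        X, y = make_gaussian_dataset(np.random.default_rng(4),
                                     separation=10.0)
        report, cm, skipped = leave_one_sample_out((X, y))
        assert report.f1 > 0.98
        assert skipped == 0

    def test_confusion_conservation(self, gaussian_dataset):
        X, y = gaussian_dataset
        report, cm, skipped = leave_one_sample_out((X, y))
        assert cm.total + skipped == y.size

    def test_shuffled_labels_near_chance(self):
        X, y = make_gaussian_dataset(np.random.default_rng(5),
                                     n_per_class=50, separation=8.0)
        y_perm = np.random.default_rng(6).permutation(y)
        report, _, _ = leave_one_sample_out((X, y_perm))
        # 3 balanced classes -> chance macro F1 around 1/3
        assert report.f1 < 0.5

    def test_matches_naive_refit(self):
        """Downdated sufficient statistics must equal a from-scratch refit."""
        X, y = make_gaussian_dataset(np.random.default_rng(7),
                                     n_per_class=15, separation=2.0)
        fast_report, fast_cm, _ = leave_one_sample_out((X, y))
        cm = ConfusionMatrix.empty(np.unique(y))
        for i in range(y.size):
            mask = np.arange(y.size) != i
            model = fit_qda(X[mask], y[mask])
            cm.add([y[i]], [predict_qda(model, X[i])])
        np.testing.assert_array_equal(fast_cm.counts, cm.counts)


class TestLeaveOneSubjectOut:
    def _dataset(self, rng, n_subjects=6, per_subject=20, offset=0.0):
        X, y, subj = [], [], []
        for s in range(n_subjects):
            xs, ys = make_gaussian_dataset(rng, n_per_class=per_subject // 2,
                                           n_classes=2, separation=6.0)
            X.append(xs + offset * rng.standard_normal())
            y.append(ys)
            subj += [s] * len(ys)
        return (np.vstack(X), np.concatenate(y), np.asarray(subj))

    def test_every_sample_tested_once(self):
        data = self._dataset(np.random.default_rng(8))
        report, cm, skipped = leave_one_subject_out(data)
        assert cm.total == data[1].size

    def test_homogeneous_close_to_loo(self):
        X, y, subj = self._dataset(np.random.default_rng(9))
        loso, _, _ = leave_one_subject_out((X, y, subj))
        loo, _, _ = leave_one_sample_out((X, y))
        assert abs(loso.f1 - loo.f1) < 0.1

    def test_requires_three_subjects(self):
        X, y = make_gaussian_dataset(np.random.default_rng(10))
        subj = np.array([0, 1] * (y.size // 2))
        with pytest.raises(DataError):
            leave_one_subject_out((X, y, subj[:y.size]))

    def test_accepts_labeled_dataset(self, gaussian_dataset):
        X, y = gaussian_dataset
        subj = np.repeat(np.arange(4), y.size // 4)
        ds = LabeledDataset(X=X, y=y, subject_ids=subj,
                            feature_names=[f"f{j}" for j in range(X.shape[1])])
        report, _, _ = leave_one_subject_out(ds)
        assert isinstance(report, ScoreReport)
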