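"""Quadratic discriminant classification, macro-F1 scoring and cross-validation.

QDA is implemented from scratch: per-class empirical priors, means and
sample covariances; prediction maximises

    log pi_l - 0.5 log|Sigma_l| - 0.5 (x - mu_l)^T Sigma_l^-1 (x - mu_l)

with deterministic tie-break to the lowest class index.  Covariances that
fail a Cholesky factorisation are ridge-regularised by
``lambda * (tr Sigma / d) * I`` with lambda escalating from 1e-6 by factors
of 10.

Leave-one-sample-out cross-validation uses sufficient-statistic downdating
(only the held-out sample's class changes between folds), which makes the
full N-fold loop cheap enough for permutation tests and feature selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .behavior import LabeledDataset
from .errors import DataError, FitError

__all__ = [
    "QdaModel",
    "ConfusionMatrix",
    "ScoreReport",
    "fit_qda",
    "predict_qda",
    "macro_scores",
    "leave_one_sample_out",
    "leave_one_subject_out",
]

log = logging.getLogger(__name__)

_RIDGE_START = 1e-6
_RIDGE_MAX = 1e3


def _regularized_cholesky(cov: np.ndarray) -> tuple:
    """Lower Cholesky factor, ridge-escalated until it succeeds.

    Returns ``(L, log_det, lambda_used)``.
    """
    d = cov.shape[0]
    scale = np.trace(cov) / d
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    lam = 0.0
    while True:
        try:
            L = cholesky(cov + lam * scale * np.eye(d), lower=True)
            log_det = 2.0 * float(np.sum(np.log(np.diag(L))))
            if np.isfinite(log_det):
                return L, log_det, lam
        except np.linalg.LinAlgError:
            pass
        except ValueError:
            pass
        lam = _RIDGE_START if lam == 0.0 else lam * 10.0
        if lam > _RIDGE_MAX:
            raise FitError("covariance not positive definite even after ridge")


@dataclass
class QdaModel:
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray          # (L, d)
    covariances: np.ndarray    # (L, d, d)
    chol: list                 # lower factors per class
    log_dets: np.ndarray
    feature_names: list | None = None

    @property
    def n_features(self) -> int:
        return int(self.means.shape[1])


def fit_qda(X, y=None, feature_names=None) -> QdaModel:
    """Fit per-class Gaussians with empirical priors.

    Accepts either a :class:`LabeledDataset` or ``(X, y)`` arrays.
    """
    if isinstance(X, LabeledDataset):
        ds = X
        X, y, feature_names = ds.X, ds.y, ds.feature_names
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DataError("X must be (n, d) aligned with y")
    classes = np.unique(y)
    if classes.size < 2:
        raise FitError("need at least 2 classes")
    n, d = X.shape
    priors = np.empty(classes.size)
    means = np.empty((classes.size, d))
    covs = np.empty((classes.size, d, d))
    chols, log_dets = [], np.empty(classes.size)
    for i, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise FitError(f"class {c!r} has fewer than 2 samples")
        priors[i] = Xc.shape[0] / n
        means[i] = Xc.mean(axis=0)
        covs[i] = np.cov(Xc, rowvar=False, ddof=1).reshape(d, d)
        L, ld, lam = _regularized_cholesky(covs[i])
        if lam > 0:
            log.debug("class %r regularized with lambda=%g", c, lam)
        chols.append(L)
        log_dets[i] = ld
    return QdaModel(classes=classes, priors=priors, means=means,
                    covariances=covs, chol=chols, log_dets=log_dets,
                    feature_names=list(feature_names) if feature_names else None)


def _discriminants(model: QdaModel, X: np.ndarray) -> np.ndarray:
    """Log-discriminant scores, shape (n, L)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise DataError(
            f"expected {model.n_features} features, got {X.shape[1]}")
    n = X.shape[0]
    scores = np.empty((n, model.classes.size))
    for i in range(model.classes.size):
        diff = X - model.means[i]
        z = solve_triangular(model.chol[i], diff.T, lower=True)
        maha = np.sum(z * z, axis=0)
        scores[:, i] = (np.log(model.priors[i]) - 0.5 * model.log_dets[i]
                        - 0.5 * maha)
    return scores


def predict_qda(model: QdaModel, X: np.ndarray) -> np.ndarray:
    """Class labels for one vector or a matrix of vectors.

    Ties break to the lowest class index (np.argmax picks the first max and
    classes are sorted ascending).
    """
    single = np.asarray(X).ndim == 1
    idx = np.argmax(_discriminants(model, X), axis=1)
    out = model.classes[idx]
    return out[0] if single else out


@dataclass
class ConfusionMatrix:
    """Counts[true, predicted] over a fixed ordered label set."""

    labels: np.ndarray
    counts: np.ndarray

    @classmethod
    def empty(cls, labels) -> "ConfusionMatrix":
        labels = np.asarray(labels)
        return cls(labels=labels,
                   counts=np.zeros((labels.size, labels.size), dtype=int))

    def add(self, y_true, y_pred) -> None:
        index = {c: i for i, c in enumerate(self.labels.tolist())}
        for t, p in zip(np.atleast_1d(y_true), np.atleast_1d(y_pred)):
            self.counts[index[t], index[p]] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ScoreReport:
    f1: float
    precision: float
    recall: float
    n_test: int
    p_value: float | None = None


def macro_scores(cm: ConfusionMatrix) -> ScoreReport:
    """Macro precision/recall and their harmonic mean.

    Classes with no true samples (P_l = 0) or never predicted contribute 0
    to the respective average, keeping scores finite on skewed folds.
    """
    counts = np.asarray(cm.counts, dtype=float)
    if counts.sum() <= 0:
        raise DataError("empty confusion matrix")
    L = counts.shape[0]
    tp = np.diag(counts)
    p_true = counts.sum(axis=1)
    p_pred = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rec_terms = np.where(p_true > 0, tp / np.where(p_true > 0, p_true, 1), 0.0)
        prec_terms = np.where(p_pred > 0, tp / np.where(p_pred > 0, p_pred, 1), 0.0)
    recall = float(rec_terms.sum() / L)
    precision = float(prec_terms.sum() / L)
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return ScoreReport(f1=f1, precision=precision, recall=recall,
                       n_test=cm.total)


class _LooEngine:
    """Sufficient-statistic machinery for fast leave-one-sample-out folds.

    Full-data per-class statistics are computed once; for the fold holding
    out sample i only the statistics of i's class change and are downdated
    in O(d^2); the other classes re-use their full-data Cholesky factors.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.classes = np.unique(self.y)
        self.n, self.d = self.X.shape
        self.class_idx = {c: i for i, c in enumerate(self.classes.tolist())}
        self.counts = np.array([(self.y == c).sum() for c in self.classes])
        self.sums = np.stack([self.X[self.y == c].sum(axis=0)
                              for c in self.classes])
        self.outers = np.stack([self.X[self.y == c].T @ self.X[self.y == c]
                                for c in self.classes])
        self.full_means = self.sums / self.counts[:, None]
        self.full_chol, self.full_logdet = [], []
        for i, c in enumerate(self.classes):
            nc = self.counts[i]
            cov = (self.outers[i] - nc * np.outer(self.full_means[i],
                                                  self.full_means[i]))
            cov = cov / max(nc - 1, 1)
            L, ld, _ = _regularized_cholesky(cov)
            self.full_chol.append(L)
            self.full_logdet.append(ld)

    def fold_scores(self, i: int, Xq: np.ndarray) -> np.ndarray | None:
        """Discriminant scores of query points under the fold-i model.

        Returns None when the fold must be skipped (held-out sample's class
        would retain < 2 training samples).
        """
        ci = self.class_idx[self.y[i]]
        n_c = self.counts[ci] - 1
        if n_c < 2:
            return None
        x = self.X[i]
        mean_c = (self.sums[ci] - x) / n_c
        cov_c = (self.outers[ci] - np.outer(x, x)
                 - n_c * np.outer(mean_c, mean_c)) / (n_c - 1)
        L_c, ld_c, _ = _regularized_cholesky(cov_c)
        n_train = self.n - 1
        Xq = np.atleast_2d(Xq)
        scores = np.empty((Xq.shape[0], self.classes.size))
        for k in range(self.classes.size):
            if k == ci:
                mean, L, ld, nk = mean_c, L_c, ld_c, n_c
            else:
                mean, L, ld, nk = (self.full_means[k], self.full_chol[k],
                                   self.full_logdet[k], self.counts[k])
            diff = Xq - mean
            z = solve_triangular(L, diff.T, lower=True)
            scores[:, k] = (np.log(nk / n_train) - 0.5 * ld
                            - 0.5 * np.sum(z * z, axis=0))
        return scores

    def fold_predict(self, i: int, Xq: np.ndarray) -> np.ndarray | None:
        scores = self.fold_scores(i, Xq)
        if scores is None:
            return None
        return self.classes[np.argmax(scores, axis=1)]


def _as_arrays(dataset) -> tuple:
    if isinstance(dataset, LabeledDataset):
        return dataset.X, dataset.y, dataset.subject_ids
    X, y = dataset
    return np.asarray(X, float), np.asarray(y), None


def leave_one_sample_out(dataset) -> tuple:
    """LOO cross-validation; returns ``(ScoreReport, ConfusionMatrix, n_skipped)``.

    Folds whose training set would lose a class (the held-out sample's class
    has < 3 members, leaving < 2 for covariance estimation) are skipped and
    counted.
    """
    X, y, _ = _as_arrays(dataset)
    engine = _LooEngine(X, y)
    cm = ConfusionMatrix.empty(engine.classes)
    skipped = 0
    for i in range(engine.n):
        pred = engine.fold_predict(i, X[i])
        if pred is None:
            skipped += 1
            continue
        cm.add([y[i]], pred)
    if skipped:
        log.warning("leave-one-sample-out: skipped %d folds", skipped)
    return macro_scores(cm), cm, skipped


def leave_one_subject_out(dataset) -> tuple:
    """One fold per subject (the "population model" scheme)."""
    if isinstance(dataset, LabeledDataset):
        X, y, subjects = dataset.X, dataset.y, dataset.subject_ids
    else:
        X, y, subjects = dataset
        X, y, subjects = np.asarray(X, float), np.asarray(y), np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 3:
        raise DataError("leave-one-subject-out requires >= 3 subjects")
    cm = ConfusionMatrix.empty(np.unique(y))
    skipped = 0
    for s in uniq:
        test = subjects == s
        train = ~test
        y_train = y[train]
        # classes too sparse to estimate a covariance are dropped from the
        # fold's training set; the fold is skipped if < 2 classes survive
        labels, counts = np.unique(y_train, return_counts=True)
        viable = labels[counts >= 2]
        if viable.size < 2:
            skipped += 1
            continue
        keep = np.isin(y_train, viable)
        model = fit_qda(X[train][keep], y_train[keep])
        preds = np.atleast_1d(predict_qda(model, X[test]))
        # labels absent from this training fold still count as errors
        cm.add(y[test], preds)
    if skipped:
        log.warning("leave-one-subject-out: skipped %d subject folds", skipped)
    return macro_scores(cm), cm, skipped


def loo_f1(X, y) -> float:
    """Convenience scorer used by selection and permutation routines."""
    report, _, _ = leave_one_sample_out((X, y))
    return report.f1
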