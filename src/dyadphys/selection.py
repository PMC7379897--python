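"""Backward feature selection, permutation importance and significance tests.

* Backward selection greedily removes the feature whose omission most
  increases the leave-one-sample-out macro-F1, stopping when no removal
  strictly improves the score (or one feature remains).
* Permutation importance replaces, for every sample, the value of one
  feature with the values from every other sample, yielding N(N-1)
  evaluations; the drop in macro-F1 relative to baseline measures the
  feature's importance.  Training happens once per left-out original sample
  (N trainings), each model scoring that sample's N-1 substituted variants.
* The label-permutation test destroys the feature-label structure n_perm
  times and reports the +1-corrected exceedance probability.
* Benjamini-Hochberg step-up controls the false discovery rate across a
  family of such p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .behavior import LabeledDataset
from .errors import DataError
from .qda import ConfusionMatrix, _LooEngine, leave_one_sample_out, macro_scores

__all__ = [
    "SelectionTrace",
    "ImportanceEntry",
    "backward_select",
    "permutation_importance",
    "permutation_test",
    "fdr_adjust_suite",
]

log = logging.getLogger(__name__)


def _xy(dataset) -> tuple:
    if isinstance(dataset, LabeledDataset):
        return dataset.X, dataset.y, list(dataset.feature_names)
    X, y = dataset
    X = np.asarray(X, float)
    return X, np.asarray(y), [f"f{j}" for j in range(X.shape[1])]


def _default_scorer(X: np.ndarray, y: np.ndarray) -> float:
    report, _, _ = leave_one_sample_out((X, y))
    return report.f1


@dataclass
class SelectionTrace:
    """Record of one greedy backward-selection run."""

    steps: list = field(default_factory=list)   # (removed feature, F1 after)
    final_features: list = field(default_factory=list)
    final_f1: float = 0.0
    initial_f1: float = 0.0


def backward_select(dataset, scorer=None) -> SelectionTrace:
    """Greedy backward elimination on leave-one-sample-out macro-F1."""
    X, y, names = _xy(dataset)
    if X.shape[1] < 1:
        raise DataError("no features to select from")
    scorer = scorer or _default_scorer
    active = list(range(X.shape[1]))
    current = scorer(X[:, active], y)
    trace = SelectionTrace(initial_f1=current)
    while len(active) > 1:
        best_j, best_f1 = None, current
        for j in active:
            cand = [k for k in active if k != j]
            f1 = scorer(X[:, cand], y)
            if f1 > best_f1:
                best_j, best_f1 = j, f1
        if best_j is None:
            break
        active.remove(best_j)
        current = best_f1
        trace.steps.append((names[best_j], best_f1))
    trace.final_features = [names[j] for j in active]
    trace.final_f1 = current
    return trace


@dataclass
class ImportanceEntry:
    feature: str
    delta_f1: float
    baseline_f1: float


def permutation_importance(dataset, feature, baseline_f1: float | None = None,
                           max_variants: int | None = None,
                           seed: int | None = None) -> ImportanceEntry:
    """F1 decrease when one feature's values are exchanged across samples.

    For each original sample i a model is trained on the other N-1 samples
    and evaluated on the N-1 copies of sample i carrying the feature value
    of every other sample (optionally subsampled to ``max_variants`` per
    sample for large N).
    """
    X, y, names = _xy(dataset)
    if isinstance(feature, str):
        j = names.index(feature)
        fname = feature
    else:
        j = int(feature)
        fname = names[j]
    n = X.shape[0]
    if baseline_f1 is None:
        baseline_f1 = _default_scorer(X, y)
    engine = _LooEngine(X, y)
    cm = ConfusionMatrix.empty(engine.classes)
    rng = np.random.default_rng(seed)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        if max_variants is not None and others.size > max_variants:
            others = rng.choice(others, size=max_variants, replace=False)
        variants = np.repeat(X[i][None, :], others.size, axis=0)
        variants[:, j] = X[others, j]
        preds = engine.fold_predict(i, variants)
        if preds is None:
            continue
        cm.add(np.full(others.size, y[i]), preds)
    permuted = macro_scores(cm).f1
    return ImportanceEntry(feature=fname, delta_f1=baseline_f1 - permuted,
                           baseline_f1=baseline_f1)


def permutation_test(dataset, scorer=None, n_perm: int = 1000,
                     seed: int | None = None,
                     observed_f1: float | None = None) -> float:
    """+1-corrected label-permutation p-value for the observed macro-F1.

    p = (1 + #{permuted F1 >= observed F1}) / (n_perm + 1); a perfectly
    separable dataset therefore floors at 1/(n_perm + 1), never 0.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    X, y, _ = _xy(dataset)
    scorer = scorer or _default_scorer
    if observed_f1 is None:
        observed_f1 = scorer(X, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        try:
            if scorer(X, y_perm) >= observed_f1:
                exceed += 1
        except DataError:
            # a permutation can starve a class below the fit minimum
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def fdr_adjust_suite(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns a boolean rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DataError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = q * (np.arange(1, m + 1) / m)
    below = np.nonzero(ranked <= thresholds)[0]
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask
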