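"""Correlation analyses between ratings, partners and tracking errors.

Per-dyad rating-rating Pearson correlations (collaborative condition),
per-subject rating-error correlations, a Wilcoxon signed-rank test for
"median of the correlation distribution differs from zero", and the paired
t-test used on condition-wise tracking errors.  FDR correction re-uses the
Benjamini-Hochberg step-up from :mod:`dyadphys.selection`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, InsufficientDataError
from .selection import fdr_adjust_suite

__all__ = [
    "CorrelationRecord",
    "pearson_r",
    "dyad_rating_correlations",
    "subject_rating_error_correlations",
    "distribution_median_test",
    "paired_t_test",
]

RATING_KINDS = ("R1", "R2", "R3")


@dataclass(frozen=True)
class CorrelationRecord:
    unit: object          # dyad or subject id
    pair: str             # e.g. "R1:R2" or "R3:err_euclid"
    r: float
    p: float
    n: int


def pearson_r(x, y) -> tuple:
    """Sample Pearson correlation with a two-sided t-transform p-value.

    Zero variance in either input yields the (nan, nan) sentinel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("pearson_r inputs must have equal length")
    if x.size < 3:
        raise InsufficientDataError("pearson_r requires n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan"), float("nan")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _paired_trials(group: pd.DataFrame) -> pd.DataFrame | None:
    """Pivot one dyad's collaborative trials into partner-aligned columns."""
    subjects = sorted(group["subject"].unique())
    if len(subjects) != 2:
        return None
    a = group[group["subject"] == subjects[0]].set_index(["day", "trial"])
    b = group[group["subject"] == subjects[1]].set_index(["day", "trial"])
    common = a.index.intersection(b.index)
    if common.empty:
        return None
    cols = {}
    for kind in RATING_KINDS:
        cols[f"{kind}_a"] = a.loc[common, kind].to_numpy(dtype=float)
        cols[f"{kind}_b"] = b.loc[common, kind].to_numpy(dtype=float)
    return pd.DataFrame(cols)


def dyad_rating_correlations(table: pd.DataFrame, q: float = 0.05,
                             min_trials: int = 3) -> pd.DataFrame:
    """All R1-R3 cross-partner correlations per dyad, with FDR flags.

    FDR families are defined per rating pair (one histogram panel each).
    Dyads with too few paired trials are skipped.
    """
    collab = table[table["condition"] == "collaborative"]
    records = []
    for dyad, group in collab.groupby("dyad"):
        paired = _paired_trials(group)
        if paired is None or len(paired) < min_trials:
            continue
        for ka, kb in product(RATING_KINDS, RATING_KINDS):
            r, p = pearson_r(paired[f"{ka}_a"], paired[f"{kb}_b"])
            records.append({"dyad": dyad, "pair": f"{ka}:{kb}", "r": r,
                            "p": p, "n": len(paired)})
    out = pd.DataFrame(records)
    if out.empty:
        return out
    out["significant"] = False
    for pair, idx in out.groupby("pair").groups.items():
        pvals = out.loc[idx, "p"].to_numpy()
        finite = np.isfinite(pvals)
        mask = np.zeros(len(pvals), dtype=bool)
        if finite.any():
            mask[finite] = fdr_adjust_suite(pvals[finite], q=q)
        out.loc[idx, "significant"] = mask
    return out


def subject_rating_error_correlations(table: pd.DataFrame, q: float = 0.05,
                                      min_trials: int = 3) -> pd.DataFrame:
    """Per-subject correlations between each rating and its matched error.

    Panels: R1 (collaborative) vs own-axis error, R2 vs partner-axis error,
    R3 vs Euclidean error, R1 (individual) vs own-axis error.  Subjects with
    constant ratings propagate the nan sentinel and are excluded from any
    downstream distribution test by the caller.
    """
    panels = [
        ("R1", "collaborative", "own"),
        ("R2", "collaborative", "partner"),
        ("R3", "collaborative", "euclid"),
        ("R1", "individual", "own"),
    ]
    records = []
    for kind, condition, which in panels:
        sub = table[table["condition"] == condition]
        for subject, group in sub.groupby("subject"):
            ratings = group[kind].to_numpy(dtype=float)
            ok = np.isfinite(ratings)
            if ok.sum() < min_trials:
                continue
            if which == "euclid":
                err = group["err_euclid"].to_numpy(dtype=float)
            else:
                own_axis = group["axis"].iloc[0]
                axis = own_axis if which == "own" else ("y" if own_axis == "x" else "x")
                err = group[f"err_{axis}"].to_numpy(dtype=float)
            r, p = pearson_r(ratings[ok], err[ok])
            records.append({"subject": subject, "panel": f"{kind}_{condition}",
                            "pair": f"{kind}:err_{which}", "r": r, "p": p,
                            "n": int(ok.sum())})
    out = pd.DataFrame(records)
    if out.empty:
        return out
    out["significant"] = False
    for panel, idx in out.groupby("panel").groups.items():
        pvals = out.loc[idx, "p"].to_numpy()
        finite = np.isfinite(pvals)
        mask = np.zeros(len(pvals), dtype=bool)
        if finite.any():
            mask[finite] = fdr_adjust_suite(pvals[finite], q=q)
        out.loc[idx, "significant"] = mask
    return out


def _signed_rank_statistic(values: np.ndarray) -> tuple:
    """W+ statistic and the midranks used, after dropping zeros."""
    d = values[values != 0.0]
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks, d


def _exact_signed_rank_p(w_plus: float, n: int) -> float:
    """Exact two-sided p via the generating function of W+ (no ties)."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()  # == 2**n
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum() / total
    p_ge = counts[w:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def distribution_median_test(values, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank test of median zero.

    Zeros are dropped (standard signed-rank convention).  The exact null
    distribution is enumerated for n <= ``exact_max_n`` when the absolute
    values are tie-free; otherwise a normal approximation with continuity
    and tie correction is used.
    """
    values = np.asarray(values, dtype=float)
    if np.all(values == 0.0):
        raise DataError("all values are zero; signed-rank test undefined")
    w_plus, ranks, d = _signed_rank_statistic(values)
    n = d.size
    if n < 5:
        raise InsufficientDataError("signed-rank test requires >= 5 nonzero values")
    has_ties = np.unique(np.abs(d)).size < n
    if n <= exact_max_n and not has_ties:
        return _exact_signed_rank_p(w_plus, n)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0.0:
        raise DataError("zero variance in signed-rank null")
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def paired_t_test(a, b) -> tuple:
    """Two-sided paired t-test; (nan, nan) sentinel on zero-variance diffs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise DataError("paired_t_test inputs must have equal length")
    if a.size < 2:
        raise InsufficientDataError("paired_t_test requires n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        return float("nan"), float("nan")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
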