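"""Objective tracking errors, rating preprocessing and dataset assembly.

Rating preprocessing follows two rules applied per (rating kind, condition)
family:

1. Outlier correction — a subject whose median rating lies more than 1.5
   interquartile ranges outside the quartiles of all subjects' medians has
   every rating shifted by the difference between their own median and the
   median of the remaining subjects' medians (rounded, clipped to the scale).
2. Level selection — only trials whose (corrected) rating falls among the
   L = 6 most frequent levels are kept.

Features are pooled across subjects and min-max normalised to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ProtocolError

__all__ = [
    "TrackingTrace",
    "ObjectiveError",
    "LabeledDataset",
    "tracking_errors",
    "error_for_rating",
    "correct_rating_outliers",
    "select_rating_levels",
    "assemble_dataset",
    "RATING_SCALE",
]

log = logging.getLogger(__name__)

RATING_SCALE = (1, 9)
DEFAULT_N_LEVELS = 6


@dataclass(frozen=True)
class TrackingTrace:
    """Logged ball and target pixel positions."""

    times: np.ndarray
    ball_x: np.ndarray
    ball_y: np.ndarray
    target_x: np.ndarray
    target_y: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("times", "ball_x", "ball_y", "target_x", "target_y"):
            a = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = a
            if n is None:
                n = a.size
            elif a.size != n:
                raise DataError(f"tracking column {name} length mismatch")
            object.__setattr__(self, name, a)
        if n == 0:
            raise DataError("tracking trace is empty")
        if np.any(np.diff(arrays["times"]) <= 0):
            raise DataError("tracking times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ObjectiveError:
    """Cumulative ball-target distances over a trial, in pixels."""

    euclid_cum: float
    x_cum: float
    y_cum: float


def tracking_errors(trace: TrackingTrace) -> ObjectiveError:
    """Per-sample cumulative Euclidean / |dx| / |dy| ball-target distance."""
    dx = trace.ball_x - trace.target_x
    dy = trace.ball_y - trace.target_y
    return ObjectiveError(
        euclid_cum=float(np.sum(np.hypot(dx, dy))),
        x_cum=float(np.sum(np.abs(dx))),
        y_cum=float(np.sum(np.abs(dy))),
    )


def error_for_rating(kind: str, axis: str, err: ObjectiveError,
                     condition: str = "collaborative") -> float:
    """Map a rating kind to the tracking error it is predicted from.

    R1 uses the axis the subject controls, R2 the partner's axis, R3 the
    Euclidean distance.  R2/R3 only exist in the collaborative condition.
    """
    if kind not in ("R1", "R2", "R3"):
        raise ProtocolError(f"unknown rating kind {kind!r}")
    if axis not in ("x", "y"):
        raise ProtocolError(f"axis must be 'x' or 'y', got {axis!r}")
    if kind in ("R2", "R3") and condition != "collaborative":
        raise ProtocolError(f"{kind} is only collected after collaborative trials")
    if kind == "R3":
        return err.euclid_cum
    own = err.x_cum if axis == "x" else err.y_cum
    partner = err.y_cum if axis == "x" else err.x_cum
    return own if kind == "R1" else partner


def correct_rating_outliers(ratings: pd.Series, subjects: pd.Series,
                            scale: tuple = RATING_SCALE) -> tuple:
    """Shift ratings of subjects whose median is a Tukey-fence outlier.

    Quartiles (linear interpolation) and the 1.5-IQR fences are computed on
    the set of per-subject medians.  A flagged subject's every rating is
    shifted by -(own median - median of the other subjects' medians),
    rounded to the nearest integer and clipped to the rating scale.

    Returns ``(corrected ratings, report)`` where the report maps corrected
    subject id -> applied integer shift.
    """
    ratings = pd.Series(np.asarray(ratings, dtype=float))
    subjects = pd.Series(np.asarray(subjects))
    if ratings.size != subjects.size:
        raise DataError("ratings/subjects length mismatch")
    medians = ratings.groupby(subjects.values).median()
    if medians.size < 3:
        raise DataError("outlier correction requires >= 3 subjects")
    q1, q3 = np.percentile(medians.values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    corrected = ratings.copy()
    report: dict = {}
    for subj, med in medians.items():
        if lo <= med <= hi:
            continue
        others = medians.drop(subj)
        shift = float(np.median(others.values)) - med
        mask = (subjects == subj).values
        corrected[mask] = np.clip(np.rint(ratings[mask] + shift), *scale)
        report[subj] = shift
    return corrected.astype(int), report


def select_rating_levels(ratings: pd.Series, n_levels: int = DEFAULT_N_LEVELS) -> tuple:
    """Keep only samples whose rating is among the most frequent levels.

    Ties at the cut are broken deterministically: prefer the level closer to
    the grand median of all ratings, then the lower level.

    Returns ``(boolean keep mask, sorted retained levels)``.
    """
    ratings = pd.Series(np.asarray(ratings))
    counts = ratings.value_counts()
    grand_median = float(ratings.median())
    order = sorted(
        counts.index,
        key=lambda lv: (-counts[lv], abs(lv - grand_median), lv),
    )
    retained = sorted(order[:n_levels])
    keep = ratings.isin(retained).values
    return keep, retained


@dataclass
class LabeledDataset:
    """Pooled normalised feature matrix with aligned labels and subject ids."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    feature_names: list
    rating_kind: str = ""
    condition: str = ""
    retained_levels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.X.ndim != 2:
            raise DataError("feature matrix must be 2-D")
        if not (self.X.shape[0] == self.y.size == self.subject_ids.size):
            raise DataError("feature/label/subject lengths disagree")
        if self.X.shape[1] != len(self.feature_names):
            raise DataError("feature_names length mismatch")

    @property
    def n(self) -> int:
        return int(self.y.size)

    def subset_features(self, names: list) -> "LabeledDataset":
        idx = [self.feature_names.index(nm) for nm in names]
        return LabeledDataset(
            X=self.X[:, idx], y=self.y, subject_ids=self.subject_ids,
            feature_names=list(names), rating_kind=self.rating_kind,
            condition=self.condition, retained_levels=list(self.retained_levels),
        )


def _minmax(X: np.ndarray, feature_names: list) -> np.ndarray:
    out = np.empty_like(X, dtype=float)
    for j, name in enumerate(feature_names):
        col = X[:, j].astype(float)
        if np.any(~np.isfinite(col)):
            med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            log.warning("feature %s: imputing %d non-finite values with median",
                        name, int(np.sum(~np.isfinite(col))))
            col = np.where(np.isfinite(col), col, med)
        lo, hi = col.min(), col.max()
        if hi > lo:
            out[:, j] = (col - lo) / (hi - lo)
        else:
            log.warning("feature %s is constant; mapped to 0", name)
            out[:, j] = 0.0
    return out


def assemble_dataset(table: pd.DataFrame, kind: str, condition: str,
                     predictor: str, feature_columns: list,
                     n_levels: int = DEFAULT_N_LEVELS,
                     correct_outliers: bool = True) -> LabeledDataset:
    """Build the pooled labeled dataset for one analysis cell.

    Parameters
    ----------
    table : DataFrame
        One row per subject-trial with identifier columns (``subject``,
        ``condition``, ``axis``), rating columns (``R1``..), per-trial error
        columns (``err_x``, ``err_y``, ``err_euclid``) and the autonomic
        feature columns.
    kind, condition : str
        Rating kind (R1/R2/R3) and condition of the cell.
    predictor : str
        ``"autonomic"`` (the full feature set) or ``"objective"`` (the single
        kind-matched tracking-error column).
    """
    if predictor not in ("autonomic", "objective"):
        raise ProtocolError(f"unknown predictor {predictor!r}")
    if kind in ("R2", "R3") and condition != "collaborative":
        raise ProtocolError(f"{kind} is only available in the collaborative condition")
    sub = table[table["condition"] == condition].copy()
    sub = sub[np.isfinite(sub[kind].astype(float))]
    if sub.empty:
        raise DataError(f"no samples for {kind}/{condition}")

    ratings = sub[kind].astype(float)
    if correct_outliers:
        ratings, _ = correct_rating_outliers(ratings, sub["subject"])
    ratings = pd.Series(np.asarray(ratings), index=sub.index)
    keep, retained = select_rating_levels(ratings, n_levels=n_levels)
    sub = sub[keep]
    ratings = ratings[keep]

    if predictor == "autonomic":
        names = list(feature_columns)
        raw = sub[names].to_numpy(dtype=float)
    else:
        err = np.array([
            error_for_rating(kind, row.axis,
                             ObjectiveError(row.err_euclid, row.err_x, row.err_y),
                             condition)
            for row in sub.itertuples()
        ])
        names = [f"tracking_error_{kind}"]
        raw = err[:, None]

    missing = ~np.isfinite(raw).all(axis=1)
    if predictor == "objective" and missing.any():
        raise DataError("missing tracking error for a retained trial")
    X = _minmax(raw, names)
    return LabeledDataset(
        X=X, y=np.asarray(ratings, dtype=int),
        subject_ids=sub["subject"].to_numpy(),
        feature_names=names, rating_kind=kind, condition=condition,
        retained_levels=[int(v) for v in retained],
    )
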