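"""End-to-end orchestration: simulate -> features -> prep -> classify -> report.

The analysis grid covers four rating/condition cells (R1-collaborative, R2,
R3, R1-individual), two predictor sets (aggregated autonomic parameters vs
the single matched tracking error) and two cross-validation schemes
(leave-one-sample-out, leave-one-subject-out) — 16 score rows in total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import hrv, resp_eda
from .behavior import assemble_dataset, tracking_errors
from .errors import ConfigError, DataError
from .qda import leave_one_sample_out, leave_one_subject_out
from .selection import backward_select, permutation_importance, permutation_test
from .stats import dyad_rating_correlations, subject_rating_error_correlations
from .synthetic import CohortConfig, TrialRecord, generate_cohort

__all__ = [
    "RunConfig",
    "FEATURE_COLUMNS",
    "CELLS",
    "trial_features",
    "build_trial_table",
    "run_pipeline",
    "classify_cells",
    "single_parameter_sweep",
    "report_tables",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = (hrv.HRV_COLUMNS + resp_eda.RESP_COLUMNS
                   + resp_eda.EDA_COLUMNS)

# (rating kind, condition) cells of the analysis, in reporting order
CELLS = (
    ("R1", "collaborative"),
    ("R2", "collaborative"),
    ("R3", "collaborative"),
    ("R1", "individual"),
)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cells: tuple = CELLS
    predictors: tuple = ("autonomic", "objective")
    cv_schemes: tuple = ("sample", "subject")
    n_perm: int = 0                # 0 disables the permutation test
    perm_seed: int = 0
    run_selection: bool = False
    run_importance: bool = False
    outdir: str = "results"

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        cohort_payload = payload.pop("cohort", {})
        known_cohort = {f.name for f in dc_fields(CohortConfig)}
        bad = set(cohort_payload) - known_cohort
        if bad:
            raise ConfigError(f"unknown cohort config fields: {sorted(bad)}")
        if "rating_scale" in cohort_payload:
            cohort_payload["rating_scale"] = tuple(cohort_payload["rating_scale"])
        cohort = CohortConfig(**cohort_payload)
        known = {f.name for f in dc_fields(cls)} - {"cohort"}
        bad = set(payload) - known
        if bad:
            raise ConfigError(f"unknown run config fields: {sorted(bad)}")
        if "cells" in payload:
            payload["cells"] = tuple(tuple(c) for c in payload["cells"])
        for key in ("predictors", "cv_schemes"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(cohort=cohort, **payload)


def trial_features(rec: TrialRecord) -> dict:
    """All 23 autonomic parameters for one trial record."""
    nn = hrv.NNSeries.from_rpeaks(rec.rpeaks)
    out = dict(hrv.hrv_features(nn))
    out.update(resp_eda.resp_features(rec.resp, rec.fs))
    out.update(resp_eda.eda_features(rec.eda, rec.fs))
    return out


def build_trial_table(records: list) -> pd.DataFrame:
    """One row per subject-trial: ids, ratings, tracking errors, features."""
    rows = []
    for rec in records:
        err = tracking_errors(rec.tracking)
        row = {
            "dyad": rec.dyad_id, "subject": rec.subject_id, "day": rec.day,
            "condition": rec.condition, "trial": rec.trial_index,
            "axis": rec.axis,
            "R1": rec.ratings.get("R1", np.nan),
            "R2": rec.ratings.get("R2", np.nan),
            "R3": rec.ratings.get("R3", np.nan),
            "err_x": err.x_cum, "err_y": err.y_cum,
            "err_euclid": err.euclid_cum,
        }
        row.update(trial_features(rec))
        rows.append(row)
    return pd.DataFrame(rows)


def _run_cv(dataset, scheme: str):
    if scheme == "sample":
        return leave_one_sample_out(dataset)
    if scheme == "subject":
        return leave_one_subject_out(dataset)
    raise ConfigError(f"unknown cv scheme {scheme!r}")


def classify_cells(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Score every (cell x predictor x cv) combination of the run config."""
    rows = []
    for kind, condition in cfg.cells:
        for predictor in cfg.predictors:
            try:
                ds = assemble_dataset(table, kind, condition, predictor,
                                      feature_columns=list(FEATURE_COLUMNS))
            except DataError as exc:
                log.warning("cell %s/%s/%s skipped: %s", kind, condition,
                            predictor, exc)
                continue
            for scheme in cfg.cv_schemes:
                report, _, skipped = _run_cv(ds, scheme)
                p = np.nan
                if cfg.n_perm > 0:
                    def scorer(X, y):
                        if scheme == "sample":
                            return leave_one_sample_out((X, y))[0].f1
                        return leave_one_subject_out((X, y, ds.subject_ids))[0].f1
                    p = permutation_test((ds.X, ds.y), scorer=scorer,
                                         n_perm=cfg.n_perm,
                                         seed=cfg.perm_seed,
                                         observed_f1=report.f1)
                rows.append({
                    "rating": kind, "condition": condition,
                    "predictor": predictor, "cv": scheme,
                    "F1": report.f1, "p": p,
                    "precision": report.precision, "recall": report.recall,
                    "n": ds.n, "skipped_folds": skipped,
                })
    return pd.DataFrame(rows)


def single_parameter_sweep(table: pd.DataFrame, kind: str, condition: str,
                           cv: str = "sample") -> pd.DataFrame:
    """Leave-one-sample-out F1 for each autonomic parameter individually."""
    rows = []
    for name in FEATURE_COLUMNS:
        ds = assemble_dataset(table, kind, condition, "autonomic",
                              feature_columns=list(FEATURE_COLUMNS))
        ds1 = ds.subset_features([name])
        report, _, _ = _run_cv(ds1, cv)
        rows.append({"rating": kind, "condition": condition, "feature": name,
                     "F1": report.f1, "precision": report.precision,
                     "recall": report.recall})
    return pd.DataFrame(rows)


def report_tables(results: pd.DataFrame) -> dict:
    """One table per CV scheme, predictors side by side (Tables 4/5 layout)."""
    columns = ["rating", "condition", "predictor", "F1", "p", "precision",
               "recall"]
    out = {}
    for scheme in ("sample", "subject"):
        if results.empty:
            out[scheme] = pd.DataFrame(columns=columns)
            continue
        sub = results[results["cv"] == scheme]
        out[scheme] = sub[columns].reset_index(drop=True)
    return out


def run_pipeline(cfg: RunConfig, outdir=None) -> dict:
    """Execute the full analysis and write all result files.

    Returns a dict with the in-memory artifacts (trial table, score rows,
    correlation records, selection/importance tables).
    """
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(cfg.cohort)
    table = build_trial_table(records)
    table.to_csv(outdir / "features.csv", index=False)

    results = classify_cells(table, cfg)
    results.to_csv(outdir / "scores.csv", index=False)

    dyad_corr = dyad_rating_correlations(table)
    subj_corr = subject_rating_error_correlations(table)
    dyad_corr.to_csv(outdir / "dyad_correlations.csv", index=False)
    subj_corr.to_csv(outdir / "subject_error_correlations.csv", index=False)

    artifacts = {"table": table, "scores": results,
                 "dyad_correlations": dyad_corr,
                 "subject_error_correlations": subj_corr}

    if cfg.run_selection or cfg.run_importance:
        sel_rows, imp_rows = [], []
        for kind, condition in cfg.cells:
            ds = assemble_dataset(table, kind, condition, "autonomic",
                                  feature_columns=list(FEATURE_COLUMNS))
            trace = backward_select(ds)
            for feat, f1 in trace.steps:
                sel_rows.append({"rating": kind, "condition": condition,
                                 "removed": feat, "F1": f1})
            sel_rows.append({"rating": kind, "condition": condition,
                             "removed": "<final>", "F1": trace.final_f1})
            if cfg.run_importance:
                final = ds.subset_features(trace.final_features)
                for feat in trace.final_features:
                    entry = permutation_importance(final, feat,
                                                   baseline_f1=trace.final_f1)
                    imp_rows.append({"rating": kind, "condition": condition,
                                     "feature": feat,
                                     "delta_f1": entry.delta_f1})
        pd.DataFrame(sel_rows).to_csv(outdir / "selection.csv", index=False)
        artifacts["selection"] = pd.DataFrame(sel_rows)
        if cfg.run_importance:
            pd.DataFrame(imp_rows).to_csv(outdir / "importance.csv", index=False)
            artifacts["importance"] = pd.DataFrame(imp_rows)

    manifest = {
        "cohort_config": cfg.cohort.to_dict(),
        "n_perm": cfg.n_perm,
        "perm_seed": cfg.perm_seed,
        "cells": [list(c) for c in cfg.cells],
        "n_records": len(records),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts
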