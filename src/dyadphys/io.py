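"""Plain-text cohort serialisation.

Layout of a cohort directory::

    manifest.json                  config echo, seed, file index
    ratings.csv                    dyad, subject, day, condition, trial, axis, R1, R2, R3
    signals/<stem>.tsv             time_s, resp, eda, ball_x, ball_y, target_x, target_y
    signals/<stem>.rpeaks.txt      one R-peak time (seconds) per line

Ground-truth latents are deliberately NOT serialised; the on-disk cohort is
what the analysis path is allowed to see.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TrackingTrace
from .errors import DataError
from .synthetic import CohortConfig, TrialRecord

__all__ = ["write_cohort", "read_cohort", "trial_stem"]


def trial_stem(rec: TrialRecord) -> str:
    return (f"d{rec.dyad_id:02d}_s{rec.subject_id:02d}_day{rec.day}"
            f"_{rec.condition}_t{rec.trial_index:02d}")


def write_cohort(records: list, outdir, config: CohortConfig | None = None) -> Path:
    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    rows, files = [], []
    for rec in records:
        stem = trial_stem(rec)
        sig = pd.DataFrame({
            "time_s": rec.tracking.times,
            "resp": rec.resp,
            "eda": rec.eda,
            "ball_x": rec.tracking.ball_x,
            "ball_y": rec.tracking.ball_y,
            "target_x": rec.tracking.target_x,
            "target_y": rec.tracking.target_y,
        })
        sig_path = outdir / "signals" / f"{stem}.tsv"
        sig.to_csv(sig_path, sep="\t", index=False, float_format="%.6f")
        rp_path = outdir / "signals" / f"{stem}.rpeaks.txt"
        np.savetxt(rp_path, rec.rpeaks, fmt="%.6f")
        files.append(stem)
        rows.append({
            "dyad": rec.dyad_id, "subject": rec.subject_id, "day": rec.day,
            "condition": rec.condition, "trial": rec.trial_index,
            "axis": rec.axis,
            "R1": rec.ratings.get("R1", ""),
            "R2": rec.ratings.get("R2", ""),
            "R3": rec.ratings.get("R3", ""),
        })
    pd.DataFrame(rows).to_csv(outdir / "ratings.csv", index=False)
    manifest = {
        "n_records": len(records),
        "trials": files,
        "fs": records[0].fs if records else None,
        "config": config.to_dict() if config is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_cohort(indir) -> list:
    """Load a cohort directory back into trial records (no ground truth)."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    ratings = pd.read_csv(indir / "ratings.csv")
    fs = manifest["fs"]
    records = []
    for row in ratings.itertuples():
        stem = (f"d{row.dyad:02d}_s{row.subject:02d}_day{row.day}"
                f"_{row.condition}_t{row.trial:02d}")
        sig_path = indir / "signals" / f"{stem}.tsv"
        if not sig_path.exists():
            raise DataError(f"missing signal file {sig_path}")
        sig = pd.read_csv(sig_path, sep="\t")
        rpeaks = np.loadtxt(indir / "signals" / f"{stem}.rpeaks.txt", ndmin=1)
        trace = TrackingTrace(
            times=sig["time_s"].to_numpy(),
            ball_x=sig["ball_x"].to_numpy(), ball_y=sig["ball_y"].to_numpy(),
            target_x=sig["target_x"].to_numpy(),
            target_y=sig["target_y"].to_numpy())
        rat = {}
        for kind in ("R1", "R2", "R3"):
            v = getattr(row, kind)
            if pd.notna(v) and v != "":
                rat[kind] = int(v)
        records.append(TrialRecord(
            dyad_id=int(row.dyad), subject_id=int(row.subject),
            day=int(row.day), condition=str(row.condition),
            trial_index=int(row.trial), axis=str(row.axis),
            rpeaks=rpeaks, resp=sig["resp"].to_numpy(),
            eda=sig["eda"].to_numpy(), fs=fs, tracking=trace, ratings=rat))
    return records
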