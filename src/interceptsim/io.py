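"""Plain-text interchange of trial records.

A trial batch is three files in one directory: ``trials.csv`` (500 Hz finger
samples), ``targets.csv`` (the per-frame target step log) and ``meta.json``
(schema version, seeds and per-trial annotations).  Units are mm and seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import TrialRecord
from .errors import SchemaError
from .finger import FingerTrajectory
from .targets import TargetTrajectory

SCHEMA_VERSION = 1

TRIALS_COLUMNS = ["trial_id", "time_s", "finger_x_mm", "finger_y_mm", "finger_z_mm"]
TARGETS_COLUMNS = ["trial_id", "frame_index", "time_s", "target_x_mm", "step_mm"]


def write_trials(trials: list[TrialRecord], path, meta: dict | None = None) -> None:
    """Write a batch of trials to ``trials.csv`` / ``targets.csv`` /
    ``meta.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trial_rows, target_rows, annotations = [], [], {}
    for tr in trials:
        f = tr.finger
        for t, x, y, z in zip(f.times, f.x, f.y, f.z):
            trial_rows.append((tr.trial_id, t, x, y, z))
        steps = tr.target.step_sizes
        for k, (t, p) in enumerate(zip(tr.target.frame_times, tr.target.positions)):
            target_rows.append((tr.trial_id, k, t, p, steps[k] if k < len(steps) else np.nan))
        annotations[str(tr.trial_id)] = dict(
            tap_index=int(f.tap_index), **{k: v for k, v in tr.meta.items()}
        )
    pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS).to_csv(path / "trials.csv", index=False)
    pd.DataFrame(target_rows, columns=TARGETS_COLUMNS).to_csv(path / "targets.csv", index=False)
    payload = dict(schema_version=SCHEMA_VERSION, trials=annotations, **(meta or {}))
    (path / "meta.json").write_text(json.dumps(payload, indent=1))


def read_trials(path) -> tuple[list[TrialRecord], dict]:
    """Read a batch written by :func:`write_trials`; validates the schema and
    that every trial has finger samples, a target log and annotations."""
    path = Path(path)
    for name in ("trials.csv", "targets.csv", "meta.json"):
        if not (path / name).exists():
            raise SchemaError(f"missing {name} in {path}")
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {meta.get('schema_version')!r}")
    trials_df = pd.read_csv(path / "trials.csv")
    targets_df = pd.read_csv(path / "targets.csv")
    for df, cols, name in ((trials_df, TRIALS_COLUMNS, "trials.csv"),
                           (targets_df, TARGETS_COLUMNS, "targets.csv")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise SchemaError(f"{name} is missing columns {sorted(missing)}")
    finger_ids = set(trials_df["trial_id"].unique())
    target_ids = set(targets_df["trial_id"].unique())
    meta_ids = {int(k) for k in meta["trials"]}
    if finger_ids != target_ids or finger_ids != meta_ids:
        orphans = sorted(finger_ids ^ target_ids | finger_ids ^ meta_ids)
        raise SchemaError(f"trial ids inconsistent across files: {orphans}")

    records = []
    for tid, fsub in trials_df.groupby("trial_id", sort=True):
        tsub = targets_df[targets_df["trial_id"] == tid].sort_values("frame_index")
        ann = meta["trials"][str(tid)]
        steps = tsub["step_mm"].to_numpy()[:-1]
        target = TargetTrajectory(
            tsub["time_s"].to_numpy(), tsub["target_x_mm"].to_numpy(),
            np.asarray(steps, float) / (tsub["time_s"].to_numpy()[1] - tsub["time_s"].to_numpy()[0])
            if len(tsub) > 1 else np.array([]),
        )
        finger = FingerTrajectory(
            fsub["time_s"].to_numpy(), fsub["finger_x_mm"].to_numpy(),
            fsub["finger_y_mm"].to_numpy(), fsub["finger_z_mm"].to_numpy(),
            int(ann["tap_index"]),
            meta={k: v for k, v in ann.items() if k != "tap_index"},
        )
        records.append(TrialRecord(int(tid), finger, target, meta=finger.meta))
    return records, meta
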