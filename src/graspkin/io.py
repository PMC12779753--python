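"""Tab-separated table I/O (BIDS-events and confounds dialects)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import MARKERS, TrialKinematics

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_events",
    "read_events",
    "write_kinematics",
    "read_kinematics",
    "write_ground_truth",
    "read_ground_truth",
]

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "participant", "run",
                  "block", "grip_type"]


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def write_events(events: pd.DataFrame, path) -> Path:
    cols = [c for c in EVENTS_COLUMNS if c in events.columns]
    cols += [c for c in events.columns if c not in cols]
    return write_tsv(events[cols], path)


def read_events(path) -> pd.DataFrame:
    return read_tsv(path)


def write_kinematics(trials: dict, path) -> Path:
    """Write trials (mapping trial id -> TrialKinematics) to one long TSV."""
    frames = []
    for trial_id, trial in trials.items():
        frame = trial.to_long_frame()
        frame.insert(0, "trial_id", trial_id)
        frames.append(frame)
    return write_tsv(pd.concat(frames, ignore_index=True), path)


def read_kinematics(path, frame_rate_hz: float = 60.0) -> dict:
    """Read a long-format kinematics TSV back into TrialKinematics objects."""
    table = read_tsv(path)
    trials: dict = {}
    for trial_id, sub in table.groupby("trial_id", sort=False):
        markers = {}
        orientations = {}
        for marker in MARKERS:
            rows = sub[sub["marker"] == marker].sort_values("frame")
            markers[marker] = rows[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
            orientations[marker] = rows[["rx_rad", "ry_rad", "rz_rad"]].to_numpy(float)
        trials[trial_id] = TrialKinematics(
            frame_rate_hz=frame_rate_hz, markers=markers, orientations=orientations
        )
    return trials


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, tuple):
        return list(value)
    return value


def write_ground_truth(ground_truths: dict, path) -> Path:
    """JSON sidecar: one entry per trial id."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        str(tid): {k: _jsonable(v) for k, v in vars(gt).items()}
        for tid, gt in ground_truths.items()
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path) -> dict:
    from .synth import TrialGroundTruth

    payload = json.loads(Path(path).read_text())
    out = {}
    for tid, fields in payload.items():
        if fields.get("phase_boundary_frames") is not None:
            fields["phase_boundary_frames"] = tuple(fields["phase_boundary_frames"])
        out[tid] = TrialGroundTruth(**fields)
    return out
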