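"""File formats: scenario JSON, trajectory CSV, event-log JSON, summaries CSV,
WAV audio and label tables.  All formats round-trip field-for-field."""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import EpochSummary
from .kinematics import ScenarioSpec
from .simulate import EventLog, TrajectoryRecording
from .vocalization import AudioClip

__all__ = [
    "write_scenarios",
    "read_scenarios",
    "write_recording_csv",
    "read_recording_csv",
    "write_event_log",
    "read_event_log",
    "write_summaries_csv",
    "read_summaries_csv",
    "write_wav",
    "read_wav",
    "write_labels_csv",
    "read_labels_csv",
]

TRAJECTORY_COLUMNS = [
    "t",
    "head_x",
    "head_y",
    "head_fx",
    "head_fy",
    "pelvis_x",
    "pelvis_y",
    "pelvis_fx",
    "pelvis_fy",
    "threat_x",
    "threat_y",
]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_scenarios(specs, path) -> None:
    """One JSON object per scenario; batches are JSON arrays."""
    if isinstance(specs, ScenarioSpec):
        payload = _jsonable(specs.to_dict())
    else:
        payload = [_jsonable(s.to_dict()) for s in specs]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_scenarios(path):
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        return ScenarioSpec.from_dict(data)
    return [ScenarioSpec.from_dict(d) for d in data]


def write_recording_csv(recording: TrajectoryRecording, path) -> None:
    """Tidy CSV; absent threat positions become empty fields."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRAJECTORY_COLUMNS)
        for i in range(len(recording)):
            tx, ty = recording.threat_pos[i]
            row = [
                repr(float(recording.t[i])),
                repr(float(recording.head_pos[i, 0])),
                repr(float(recording.head_pos[i, 1])),
                repr(float(recording.head_forward[i, 0])),
                repr(float(recording.head_forward[i, 1])),
                repr(float(recording.pelvis_pos[i, 0])),
                repr(float(recording.pelvis_pos[i, 1])),
                repr(float(recording.pelvis_forward[i, 0])),
                repr(float(recording.pelvis_forward[i, 1])),
                "" if math.isnan(tx) else repr(float(tx)),
                "" if math.isnan(ty) else repr(float(ty)),
            ]
            w.writerow(row)


def read_recording_csv(path) -> TrajectoryRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV {path} lacks columns: {sorted(missing)}")
    return TrajectoryRecording(
        t=df["t"].to_numpy(),
        head_pos=df[["head_x", "head_y"]].to_numpy(),
        head_forward=df[["head_fx", "head_fy"]].to_numpy(),
        pelvis_pos=df[["pelvis_x", "pelvis_y"]].to_numpy(),
        pelvis_forward=df[["pelvis_fx", "pelvis_fy"]].to_numpy(),
        threat_pos=df[["threat_x", "threat_y"]].to_numpy(),
    )


def write_event_log(log: EventLog, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(log.to_dict()), indent=2))


def read_event_log(path) -> EventLog:
    return EventLog.from_dict(json.loads(Path(path).read_text()))


def write_summaries_csv(summaries: Sequence[EpochSummary], path, extra: Optional[pd.DataFrame] = None) -> None:
    """One row per epoch; missing values are empty cells.  ``extra`` columns
    (subject/condition identifiers) are prepended when given."""
    df = pd.DataFrame([s.to_dict() for s in summaries])
    if extra is not None:
        df = pd.concat([extra.reset_index(drop=True), df], axis=1)
    df.to_csv(path, index=False)


def read_summaries_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_wav(clip: AudioClip, path) -> None:
    """PCM 16-bit WAV; amplitudes are rounded to integers (a.u. preserved)."""
    from scipy.io import wavfile

    x = np.clip(np.round(clip.samples), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(clip.sample_rate), x)


def read_wav(path, label: str = "unknown") -> AudioClip:
    from scipy.io import wavfile

    rate, x = wavfile.read(str(path))
    return AudioClip(float(rate), np.asarray(x, dtype=float), label)


def write_labels_csv(rows: Sequence[tuple], path) -> None:
    """Two columns: clip path, label."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["clip", "label"])
        for clip_path, label in rows:
            w.writerow([clip_path, label])


def read_labels_csv(path) -> list:
    out = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames is None or {"clip", "label"} - set(r.fieldnames):
            raise ValueError(f"label file {path} must have 'clip' and 'label' columns")
        for row in r:
            out.append((row["clip"], row["label"]))
    return out
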