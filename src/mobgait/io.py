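"""File formats: CSV signal files with JSON sidecars, report serialisation.

A recording is stored as a CSV with columns
``t_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps`` plus a JSON sidecar
(``<name>.json``) holding subject id, foot, sampling rate and units.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .recording import CSV_COLUMNS, ImuRecording

UNITS = {"acc": "g", "gyr": "deg/s"}


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_imu(imu: ImuRecording, csv_path) -> Path:
    """Write signal CSV + JSON sidecar; returns the sidecar path."""
    csv_path = Path(csv_path)
    imu.to_frame().to_csv(csv_path, index=False, float_format="%.8g")
    meta = {
        "subject": imu.subject,
        "foot": imu.foot,
        "fs": imu.fs,
        "units": UNITS,
        "start_s": imu.start,
    }
    side = sidecar_path(csv_path)
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return side


def read_imu(csv_path) -> ImuRecording:
    """Read a signal CSV + sidecar, validating units, columns and timing."""
    csv_path = Path(csv_path)
    side = sidecar_path(csv_path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    with open(side) as fh:
        meta = json.load(fh)
    fs = float(meta.get("fs", 0.0))
    if not fs > 0:
        raise ValueError(f"sidecar {side}: sampling rate must be positive, got {fs}")
    units = meta.get("units", {})
    if units != UNITS:
        raise ValueError(f"sidecar {side}: expected units {UNITS}, got {units}")
    frame = pd.read_csv(csv_path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing column(s): {', '.join(missing)}")
    return ImuRecording.from_frame(
        frame, fs=fs, foot=meta.get("foot", "left"), subject=meta.get("subject")
    )


def write_json(obj, path) -> None:
    """Deterministic JSON dump (sorted keys, fixed layout)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
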