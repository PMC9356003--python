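"""CSV/YAML/JSON readers and writers for the pipeline's interchange formats.

Recordings travel as two CSV files: a signal table (time_s plus one column
per muscle) and a windows table (trial_id, movement, t_start_s, t_end_s,
time_constraint_s, rom_fraction).  Goniometry is a CSV with time_s,
ankle_deg, subtalar_deg; calibration maxima and configuration are YAML;
structured results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .recording import MUSCLES, Recording, TrialWindow


def write_recording(rec: Recording, signal_path: str | Path,
                    windows_path: Optional[str | Path] = None) -> None:
    df = pd.DataFrame({"time_s": rec.time})
    for k, label in enumerate(rec.channel_labels):
        df[label] = rec.signal[k]
    df.to_csv(signal_path, index=False)
    if windows_path is not None:
        write_windows(rec.windows, windows_path)


def write_windows(windows: list[TrialWindow], path: str | Path) -> None:
    rows = [{
        "trial_id": i,
        "movement": w.movement,
        "t_start_s": w.t_start,
        "t_end_s": w.t_end,
        "time_constraint_s": w.time_constraint,
        "rom_fraction": w.rom_fraction,
    } for i, w in enumerate(windows)]
    pd.DataFrame(rows, columns=["trial_id", "movement", "t_start_s", "t_end_s",
                                "time_constraint_s", "rom_fraction"]).to_csv(path, index=False)


def read_windows(path: str | Path) -> list[TrialWindow]:
    df = pd.read_csv(path)
    required = {"movement", "t_start_s", "t_end_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"windows file {path} missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        tc = row.get("time_constraint_s")
        rf = row.get("rom_fraction")
        out.append(TrialWindow(
            movement=str(row["movement"]),
            t_start=float(row["t_start_s"]),
            t_end=float(row["t_end_s"]),
            time_constraint=None if pd.isna(tc) else float(tc),
            rom_fraction=None if pd.isna(rf) else float(rf),
        ))
    return out


def read_recording(signal_path: str | Path, windows_path: Optional[str | Path] = None,
                   domain: str = "envelope") -> Recording:
    """Read a recording from the documented CSV schema, with validation."""
    df = pd.read_csv(signal_path)
    if len(df) == 0:
        raise ValueError(f"recording {signal_path} is empty")
    if "time_s" not in df.columns:
        raise ValueError(f"recording {signal_path} missing 'time_s' column")
    missing = [m for m in MUSCLES if m not in df.columns]
    if missing:
        raise ValueError(f"recording {signal_path} missing channel column(s): {missing}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"recording {signal_path} needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2
        raise ValueError(f"non-monotone time in {signal_path} at row {bad}")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"non-uniform sampling in {signal_path}")
    signal = np.vstack([df[m].to_numpy(float) for m in MUSCLES])
    windows = read_windows(windows_path) if windows_path is not None else []
    return Recording(sample_rate=1.0 / float(dt[0]), signal=signal,
                     windows=windows, channel_labels=MUSCLES, domain=domain)


def write_goniometry(gon: pd.DataFrame, path: str | Path) -> None:
    gon.to_csv(path, index=False)


def read_goniometry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_s", "ankle_deg", "subtalar_deg"):
        if col not in df.columns:
            raise ValueError(f"goniometry file {path} missing column {col!r}")
    return df


def read_calibration(path: str | Path) -> dict[str, float]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {str(k): float(v) for k, v in data.items()}


def write_calibration(maxima: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in maxima.items()}, fh)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(data: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
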