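"""File formats: signal CSV, fiducial CSV, transform JSON, config YAML.

Signal CSV layout: optional ``#key=value`` comment lines, then the header
``time_s,displacement_mm`` and one row per sample with fixed 9-decimal
formatting ('.' decimal separator, comma delimiter, LF line endings,
locale-independent).  Writing the same signal twice yields byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .registration import PointSet, RigidTransform
from .signal import Signal

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_pointset_csv",
    "write_pointset_csv",
    "read_transform_json",
    "write_transform_json",
    "load_config",
]

_HEADER = "time_s,displacement_mm"
_TIME_TOL = 1e-6


def write_signal_csv(signal: Signal, path: str | Path) -> None:
    """Write a signal with its meta as leading ``#key=value`` comments."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for key, val in signal.meta.items():
            fh.write(f"#{key}={val}\n")
        fh.write(_HEADER + "\n")
        t = signal.times
        fh.writelines(f"{t[i]:.9f},{signal.values[i]:.9f}\n"
                      for i in range(signal.n))


def read_signal_csv(path: str | Path) -> Signal:
    """Read a signal CSV, inferring dt and validating uniform sampling.

    ``#key=value`` comment lines are parsed into ``meta`` (values kept as
    strings except when they parse as numbers).  A non-uniform time column
    (tolerance 1e-6 s) or a missing header raises a format error naming the
    first offending row.
    """
    path = Path(path)
    meta: dict = {}
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.strip()
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                try:
                    meta[key] = int(val) if val.strip().lstrip("+-").isdigit() \
                        else float(val)
                except ValueError:
                    meta[key] = val
        else:
            raise ValueError(f"{path}: no header line found")
    if header != _HEADER:
        raise ValueError(f"{path}: expected header {_HEADER!r}, got {header!r}")

    df = pd.read_csv(path, skiprows=n_skip)
    if df.empty:
        raise ValueError(f"{path}: no samples")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = t[1] - t[0]
        bad = np.flatnonzero(np.abs(np.diff(t) - dt) > _TIME_TOL)
        if dt <= 0 or bad.size:
            row = int(bad[0]) + 2 if bad.size else 1
            raise ValueError(f"{path}: non-uniform time column at data row {row}")
    else:
        dt = float(meta.get("dt_s", 0.01))
    return Signal(float(t[0]), float(dt),
                  df["displacement_mm"].to_numpy(dtype=float), meta)


def write_pointset_csv(pts: PointSet, path: str | Path) -> None:
    """Fiducial CSV: ``label,x_mm,y_mm,z_mm`` with a ``#frame=`` comment."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"#frame={pts.frame}\n")
        fh.write("label,x_mm,y_mm,z_mm\n")
        for lab, p in zip(pts.labels, pts.points):
            fh.write(f"{lab},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")


def read_pointset_csv(path: str | Path) -> PointSet:
    path = Path(path)
    frame = "ct"
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if body.startswith("frame="):
                frame = body.split("=", 1)[1]
    df = pd.read_csv(path, skiprows=n_skip)
    return PointSet(list(df["label"].astype(str)),
                    df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float), frame)


def write_transform_json(T: RigidTransform, path: str | Path) -> None:
    """Transform JSON: row-major rotation, translation, scale."""
    payload = {"R": T.R.tolist(), "t": T.t.tolist(), "scale": T.scale}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_transform_json(path: str | Path) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    return RigidTransform(np.array(payload["R"]), np.array(payload["t"]),
                          float(payload.get("scale", 1.0)))


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file into a plain dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}
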