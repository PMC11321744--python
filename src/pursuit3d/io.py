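"""Trial-log CSV I/O, outcome tables and run configuration.

A trial log is a CSV with one row per frame -- timestamp, validity flag, the
two eye rays (origin + direction), the reconstructed 3D point of regard and
one xyz triple per object -- plus a JSON sidecar (``<stem>.meta.json``)
holding the trial configuration, seed and ground-truth target.  CSV was
chosen as the interchange format: no binary standard exists for gaze trial
logs at this scale and the files stay diffable and deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import geometry as geo
from .evaluation import DetectionOutcome
from .trial import SCHEMA_VERSION, TrialLog, TrialMeta

__all__ = [
    "TrialLogError",
    "write_trial_log",
    "read_trial_log",
    "write_outcomes",
    "read_outcomes",
    "RunConfig",
    "load_config",
]

_FLOAT_FMT = "%.12g"

_RAY_COLUMNS = [f"{eye}{part}_{ax}" for eye in ("l", "r") for part in ("o", "d") for ax in "xyz"]
_FIXED_COLUMNS = ["t", "valid", *_RAY_COLUMNS, "por_x", "por_y", "por_z"]


class TrialLogError(ValueError):
    """Malformed trial-log file; the message names the offending line."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trial_log(log: TrialLog, path) -> Path:
    """Write a trial to CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    data = {
        "t": log.t,
        "valid": log.valid.astype(int),
    }
    rays = np.hstack([log.left_origin, log.left_dir, log.right_origin, log.right_dir])
    for i, col in enumerate(_RAY_COLUMNS):
        data[col] = rays[:, i]
    for i, ax in enumerate("xyz"):
        data[f"por_{ax}"] = log.por[:, i]
    for lab, arr in log.objects.items():
        for i, ax in enumerate("xyz"):
            data[f"obj_{lab}_{ax}"] = arr[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(log.meta.to_dict(), indent=2))
    return path


def read_trial_log(path) -> TrialLog:
    """Read a trial log written by :func:`write_trial_log`.

    Raises :class:`TrialLogError` naming the line number for malformed rows,
    schema mismatches or non-monotone timestamps.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TrialLogError(f"{path}: {exc}") from exc
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"{path}: header missing columns {missing}")
    obj_labels = sorted({c[4:-2] for c in df.columns if c.startswith("obj_") and c[-2] == "_"})
    if not obj_labels:
        raise TrialLogError(f"{path}: no object columns found")
    required = [c for c in df.columns if not c.startswith("por_")]
    bad = df[required].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2   # header + 1-based
        raise TrialLogError(f"{path}: malformed or incomplete row at line {line}")
    t = df["t"].to_numpy(float)
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise TrialLogError(f"{path}: non-monotone timestamp at line {int(nonmono[0]) + 3}")
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise TrialLogError(f"{path}: missing metadata sidecar {meta_path.name}")
    meta = TrialMeta.from_dict(json.loads(meta_path.read_text()))
    if meta.schema_version != SCHEMA_VERSION:
        raise TrialLogError(f"{path}: unsupported schema version {meta.schema_version}")
    rays = df[_RAY_COLUMNS].to_numpy(float)
    objects = {lab: df[[f"obj_{lab}_{ax}" for ax in "xyz"]].to_numpy(float) for lab in obj_labels}
    return TrialLog(
        t=t,
        valid=df["valid"].to_numpy(int).astype(bool),
        left_origin=rays[:, 0:3], left_dir=rays[:, 3:6],
        right_origin=rays[:, 6:9], right_dir=rays[:, 9:12],
        por=df[["por_x", "por_y", "por_z"]].to_numpy(float),
        objects=objects,
        meta=meta,
    )


def write_outcomes(outcomes: Sequence[DetectionOutcome], path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(o) for o in outcomes]).to_csv(path, index=False)
    return path


def read_outcomes(path) -> list[DetectionOutcome]:
    df = pd.read_csv(path)
    out = []
    for row in df.to_dict("records"):
        for key in ("selected", "selection_frame", "selection_time"):
            if pd.isna(row.get(key)):
                row[key] = None
        if row["selection_frame"] is not None:
            row["selection_frame"] = int(row["selection_frame"])
        out.append(DetectionOutcome(**row))
    return out


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study constants."""

    sphere_radius: float = geo.SPHERE_RADIUS
    near_distance: float = geo.NEAR_DISTANCE
    near_distance_crowded: float = geo.NEAR_DISTANCE_CROWDED
    far_distance: float = geo.FAR_DISTANCE
    circular_speed_deg: float = geo.CIRCULAR_SPEED_DEG
    linear_speed: float = geo.LINEAR_SPEED
    window_size: int = 40
    frame_rate: float = 60.0
    combine: str = "mean"
    pursuit_gain: float = 0.95
    onset_latency: float = 0.12
    angular_noise_sd: float = 0.2
    invalid_rate: float = 0.01
    interocular_distance: float = 0.065
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration, filling defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.from_dict(data)
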