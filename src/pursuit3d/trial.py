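"""Trial containers: time-aligned gaze and object streams with ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .geometry import cart_to_sph, unwrap_phi

SCHEMA_VERSION = 1


@dataclass
class TrialMeta:
    """Per-trial configuration, seed and ground truth."""

    trial_id: str
    target: str
    movement: str                 # "circular" | "linear"
    center_distance: float
    sphere_radius: float
    frame_rate: float
    rest_duration: float          # s at rest before movement onset
    move_duration: float          # s of movement
    visible: tuple[str, ...]      # labels rendered for the user
    seed: Optional[int] = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = asdict(self)
        d["visible"] = list(self.visible)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMeta":
        d = dict(d)
        d["visible"] = tuple(d["visible"])
        return cls(**d)


@dataclass
class TrialLog:
    """One trial: binocular gaze samples and per-object positions per frame.

    Arrays are frame-aligned with shape ``(n_frames, ...)``.  ``por`` holds
    NaN on frames flagged invalid (tracking loss or near-parallel rays); such
    frames are dropped before any windowed computation.
    """

    t: np.ndarray                       # (N,) strictly increasing timestamps, s
    valid: np.ndarray                   # (N,) bool
    left_origin: np.ndarray             # (N, 3)
    left_dir: np.ndarray                # (N, 3) unit
    right_origin: np.ndarray            # (N, 3)
    right_dir: np.ndarray               # (N, 3) unit
    por: np.ndarray                     # (N, 3) 3D point of regard, NaN if invalid
    objects: dict[str, np.ndarray]      # label -> (N, 3)
    meta: TrialMeta

    def __post_init__(self):
        n = len(self.t)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("valid", "left_origin", "left_dir", "right_origin", "right_dir", "por"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match timestamps")
        for lab, arr in self.objects.items():
            if len(arr) != n:
                raise ValueError(f"object {lab!r} stream length does not match timestamps")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def movement_onset(self) -> float:
        return self.meta.rest_duration

    def analysis_mask(self) -> np.ndarray:
        """Valid frames at or after movement onset (windowing starts there)."""
        return self.valid & (self.t >= self.movement_onset - 1e-9)

    def analysis_series(self, object_ids=None):
        """Spherical gaze and object series for detection.

        Returns ``(t, gaze_sph, {label: obj_sph})`` restricted to valid frames
        after movement onset; yaw is unwrapped per stream so seam crossings do
        not corrupt windowed statistics.
        """
        mask = self.analysis_mask()
        t = self.t[mask]
        gaze = cart_to_sph(self.por[mask])
        gaze[:, 2] = unwrap_phi(gaze[:, 2])
        labels = list(self.objects) if object_ids is None else list(object_ids)
        objs = {}
        for lab in labels:
            s = cart_to_sph(self.objects[lab][mask])
            s[:, 2] = unwrap_phi(s[:, 2])
            objs[lab] = s
        return t, gaze, objs
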