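"""Synthetic trial generator.

Produces ground-truth-labelled trials with the statistical structure the
detectors assume: objects move on the published circular (45 deg/s on a 0.2 m
sphere) or linear (0.15 m/s from the sphere centre) trajectories, and gaze is
an idealised smooth pursuit of the target -- a first-order lag on the
target's spherical position with configurable gain and onset latency, no
catch-up saccades.  The pursued point is converted into two eye rays from
``+-IPD/2`` on the x axis; each ray direction receives independent Gaussian
angular noise (0.2 deg per axis by default, emulating the tracker error), and
frames are occasionally flagged invalid.  The binocular 3D point of regard is
then re-estimated from the noisy rays exactly as for recorded data, so depth
(vergence) errors grow with target distance as they do physically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from . import geometry as geo
from .trial import TrialLog, TrialMeta

__all__ = [
    "OBJECT_CONFIGURATIONS",
    "TrialConfig",
    "OculomotorParams",
    "simulate_trial",
    "simulate_block",
    "experiment1_block",
    "experiment2_block",
]

#: Object configurations for multi-object settings: configuration name ->
#: spawn points (circular) / movement-vector endpoints (linear).
OBJECT_CONFIGURATIONS: dict[str, tuple[str, ...]] = {
    "3A": ("lnt", "rnt", "f"),
    "3B": ("lnb", "t", "rfb"),
    "4A": ("lt", "lb", "rb", "rt"),
    "4B": ("lnb", "rnt", "lft", "rfb"),
    "5A": ("l", "b", "r", "t", "f"),
    "5B": ("lnb", "rnt", "lft", "rfb", "f"),
    "6": ("lnb", "l", "b", "r", "t", "rft"),
    "7": ("lnb", "rnt", "l", "b", "r", "lft", "rfb"),
    "8A": ("l", "b", "r", "t", "lft", "lfb", "rfb", "rft"),
    "8B": ("lnt", "lnb", "rnb", "rnt", "lf", "fb", "rf", "ft"),
    "9A": ("lt", "l", "lb", "b", "rb", "r", "rt", "t", "f"),
    "9B": ("rnb", "rn", "rnt", "lt", "l", "lb", "ft", "f", "rb"),
    "10A": ("lnt", "lnb", "rnb", "rnt", "t", "b", "lf", "fb", "rf", "ft"),
    "10B": ("nb", "nt", "lt", "l", "lb", "rb", "r", "rt", "ft", "fb"),
    "11": ("rnt", "rn", "rnb", "lt", "l", "lb", "b", "t", "rfb", "rft", "f"),
    "12A": ("lnt", "lnb", "rnb", "rnt", "l", "b", "r", "t", "lft", "lfb", "rfb", "rft"),
    "12B": ("ln", "nb", "rn", "nt", "lt", "lb", "rb", "rt", "lf", "fb", "rf", "ft"),
}

_DISTANCES = {
    "near": geo.NEAR_DISTANCE,
    "near_crowded": geo.NEAR_DISTANCE_CROWDED,
    "far": geo.FAR_DISTANCE,
}


@dataclass(frozen=True)
class OculomotorParams:
    """Idealised smooth-pursuit eye model.

    pursuit_gain
        First-order approach rate towards the (latency-shifted) target
        position per frame; 1.0 tracks exactly, < 1 lags behind.
    onset_latency
        Pursuit onset delay in seconds.
    angular_noise_sd
        Per-axis Gaussian angular noise of each eye's ray direction, degrees.
        With two independent eyes this yields ~the same RMS directional error
        of the reconstructed point of regard.
    invalid_rate
        Per-frame probability of a tracking-loss (invalid) sample.
    interocular_distance
        Eye separation in metres; drives vergence depth sensitivity.
    """

    pursuit_gain: float = 0.95
    onset_latency: float = 0.12
    angular_noise_sd: float = 0.2
    invalid_rate: float = 0.01
    interocular_distance: float = 0.065

    def __post_init__(self):
        if not 0 < self.pursuit_gain <= 1.2:
            raise ValueError("pursuit_gain must be in (0, 1.2]")
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be >= 0")
        if not 0 <= self.invalid_rate < 1:
            raise ValueError("invalid_rate must be in [0, 1)")


NOISE_FREE = OculomotorParams(pursuit_gain=1.0, onset_latency=0.0,
                              angular_noise_sd=0.0, invalid_rate=0.0)


@dataclass(frozen=True)
class TrialConfig:
    """One trial's condition: geometry, movement, object set and ground truth."""

    target: str
    movement: str = "circular"               # "circular" | "linear"
    center_distance: float = geo.NEAR_DISTANCE
    sphere_radius: float = geo.SPHERE_RADIUS
    object_labels: tuple[str, ...] = geo.SPAWN_LABELS
    visible: Optional[tuple[str, ...]] = None  # defaults to all object_labels
    frame_rate: float = 60.0
    rest_duration: float = 1.0
    move_duration: float = 4.0
    circular_speed_deg: float = geo.CIRCULAR_SPEED_DEG
    linear_speed: float = geo.LINEAR_SPEED
    seed: int = 0
    trial_id: str = "trial"

    def __post_init__(self):
        if self.movement not in ("circular", "linear"):
            raise ValueError("movement must be 'circular' or 'linear'")
        if self.target not in self.object_labels:
            raise ValueError(f"target {self.target!r} not in object set")
        if self.rest_duration <= 0 or self.move_duration <= 0:
            raise ValueError("durations must be positive")
        if self.visible is not None and not set(self.visible) <= set(self.object_labels):
            raise ValueError("visible labels must be a subset of object_labels")


def _perturb_directions(dirs: np.ndarray, sd_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors by independent N(0, sd) angles about two axes."""
    if sd_rad == 0.0:
        return dirs
    helper = np.where(np.abs(dirs[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[0.0, 1.0, 0.0]])
    e1 = np.cross(dirs, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    coef = rng.normal(0.0, sd_rad, size=(len(dirs), 2))
    out = dirs + coef[:, :1] * e1 + coef[:, 1:] * e2
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def simulate_trial(cfg: TrialConfig, eye: OculomotorParams = OculomotorParams()) -> TrialLog:
    """Simulate one trial: object kinematics, pursuit gaze, noisy eye rays, POR."""
    layout = geo.generate_spawn_points(cfg.center_distance, cfg.sphere_radius)
    n = round((cfg.rest_duration + cfg.move_duration) * cfg.frame_rate)
    t = np.arange(n) / cfg.frame_rate
    tm = np.maximum(t - cfg.rest_duration, 0.0)     # movement-phase clock

    objects: dict[str, np.ndarray] = {}
    for lab in cfg.object_labels:
        if cfg.movement == "circular":
            objects[lab] = geo.circular_position(layout, lab, tm, cfg.circular_speed_deg)
        else:
            objects[lab] = geo.linear_position(layout.points[lab], tm, cfg.linear_speed,
                                               origin=layout.center)

    # Ideal pursued point: latency-shifted, gain-filtered target position in
    # spherical coordinates (yaw unwrapped before filtering).
    targ_sph = geo.cart_to_sph(objects[cfg.target])
    targ_sph[:, 2] = geo.unwrap_phi(targ_sph[:, 2])
    t_lag = np.maximum(t - eye.onset_latency, 0.0)
    desired = np.stack([np.interp(t_lag, t, targ_sph[:, d]) for d in range(3)], axis=1)
    gaze_sph = np.empty_like(desired)
    gaze_sph[0] = desired[0]
    g = eye.pursuit_gain
    for k in range(1, n):
        gaze_sph[k] = gaze_sph[k - 1] + g * (desired[k] - gaze_sph[k - 1])
    gaze_point = geo.sph_to_cart(gaze_sph)

    half_ipd = eye.interocular_distance / 2.0
    left_origin = np.tile([-half_ipd, 0.0, 0.0], (n, 1))
    right_origin = np.tile([half_ipd, 0.0, 0.0], (n, 1))

    def _aim(origins):
        d = gaze_point - origins
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    rng = np.random.default_rng(cfg.seed)
    sd_rad = np.radians(eye.angular_noise_sd)
    left_dir = _perturb_directions(_aim(left_origin), sd_rad, rng)
    right_dir = _perturb_directions(_aim(right_origin), sd_rad, rng)
    tracked = rng.random(n) >= eye.invalid_rate

    por, por_ok = geo.por_from_rays(left_origin, left_dir, right_origin, right_dir)
    valid = tracked & por_ok
    por = np.where(valid[:, None], por, np.nan)

    meta = TrialMeta(
        trial_id=cfg.trial_id,
        target=cfg.target,
        movement=cfg.movement,
        center_distance=cfg.center_distance,
        sphere_radius=cfg.sphere_radius,
        frame_rate=cfg.frame_rate,
        rest_duration=cfg.rest_duration,
        move_duration=cfg.move_duration,
        visible=cfg.visible if cfg.visible is not None else cfg.object_labels,
        seed=cfg.seed,
    )
    return TrialLog(t=t, valid=valid, left_origin=left_origin, left_dir=left_dir,
                    right_origin=right_origin, right_dir=right_dir, por=por,
                    objects=objects, meta=meta)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_block(conditions: Sequence[TrialConfig], n_rounds: int = 3,
                   eye: OculomotorParams = OculomotorParams(), seed: int = 0,
                   randomize: bool = True) -> list[TrialLog]:
    """Simulate a block: ``n_rounds`` rounds per condition, one trial per
    object label of that condition, each round independently shuffled.

    Every trial draws its own seed from the master seed, so an identical
    master seed reproduces the block bit for bit.
    """
    master = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(master.spawn(1)[0])
    plans: list[TrialConfig] = []
    for cond in conditions:
        for _ in range(n_rounds):
            round_targets = list(cond.object_labels)
            if randomize:
                order_rng.shuffle(round_targets)
            for target in round_targets:
                plans.append(replace(cond, target=target))
    logs = []
    for i, (plan, child) in enumerate(zip(plans, master.spawn(len(plans)))):
        cfg = replace(plan, seed=_child_seed(child),
                      trial_id=f"{plan.movement}-{plan.center_distance:g}-{i:03d}")
        logs.append(simulate_trial(cfg, eye))
    return logs


def experiment1_block(distance: str = "near", movement: str = "circular",
                      n_rounds: int = 3, eye: OculomotorParams = OculomotorParams(),
                      seed: int = 0) -> list[TrialLog]:
    """A single-visible-target block: 3 rounds x 26 targets = 78 trials.

    Only the target is rendered; all 26 objects are simulated and available
    to the detectors.
    """
    cond = TrialConfig(target=geo.SPAWN_LABELS[0], movement=movement,
                       center_distance=_DISTANCES[distance], rest_duration=1.0)
    logs = simulate_block([cond], n_rounds=n_rounds, eye=eye, seed=seed)
    out = []
    for log in logs:
        log.meta.visible = (log.meta.target,)
        out.append(log)
    return out


def experiment2_block(distance: str = "near_crowded", movement: str = "circular",
                      n_repeats: int = 3, eye: OculomotorParams = OculomotorParams(),
                      seed: int = 0) -> list[TrialLog]:
    """A multi-object block: 17 object configurations x 3 repeats = 51 trials.

    Configurations run in ascending object count; within each variant the
    target is drawn at random.  The rest phase is 2 s.
    """
    master = np.random.SeedSequence(seed)
    pick_rng = np.random.default_rng(master.spawn(1)[0])
    names = list(OBJECT_CONFIGURATIONS)
    plans = []
    for name in names:
        labels = OBJECT_CONFIGURATIONS[name]
        for _ in range(n_repeats):
            target = labels[pick_rng.integers(len(labels))]
            plans.append((name, labels, target))
    logs = []
    for i, ((name, labels, target), child) in enumerate(zip(plans, master.spawn(len(plans)))):
        cfg = TrialConfig(target=target, movement=movement,
                          center_distance=_DISTANCES[distance],
                          object_labels=labels, visible=labels,
                          rest_duration=2.0, seed=_child_seed(child),
                          trial_id=f"{movement}-{name}-{i:03d}")
        logs.append(simulate_trial(cfg, eye))
    return logs
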