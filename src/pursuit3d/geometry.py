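"""Spatial conventions and target geometry for smooth-pursuit selection in an HMD.

Coordinate frame
----------------
All positions live in a head-anchored world frame: the origin is the centre of
the head-mounted display, ``+z`` points along the initial forward gaze, ``+y``
up and ``+x`` right (right-handed).  Angular position relative to the observer
is expressed in spherical coordinates ``(r, theta, phi)``:

* ``r``      -- radial distance in metres (>= 0),
* ``theta``  -- pitch/elevation in degrees, the angle above the x-z plane,
  ``theta = asin(y / r)`` in ``[-90, 90]``,
* ``phi``    -- yaw/azimuth in degrees, measured from ``+z`` within the x-z
  plane, ``phi = atan2(x, z)`` in ``(-180, 180]``.

The degenerate point ``r = 0`` maps to ``theta = phi = 0`` by convention.

Target geometry
---------------
Selectable objects spawn on a sphere (radius 0.2 m) centred on the viewing
axis.  The 26 spawn points are the radial projections of the landmarks of the
enclosed cube (8 corners, 12 edge midpoints, 6 face centres) onto the sphere.
Labels concatenate the face letters left/right (x), near/far (z) and
top/bottom (y), e.g. ``"lnt"`` for the left-near-top corner or ``"ft"`` for
the far-top edge midpoint.

Circular trajectories rotate a spawn point about one of the three principal
axes through the sphere centre at a constant angular speed (45 deg/s); linear
trajectories move an object from the sphere centre through (and beyond) a
spawn point at constant speed (0.15 m/s).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SphericalCoord",
    "GazeRay",
    "SpawnLayout",
    "SPHERE_RADIUS",
    "NEAR_DISTANCE",
    "NEAR_DISTANCE_CROWDED",
    "FAR_DISTANCE",
    "CIRCULAR_SPEED_DEG",
    "LINEAR_SPEED",
    "TARGET_DIAMETER",
    "SPAWN_LABELS",
    "DEFAULT_TRAJECTORY_AXES",
    "to_spherical",
    "to_cartesian",
    "cart_to_sph",
    "sph_to_cart",
    "unwrap_phi",
    "compute_3d_por",
    "por_from_rays",
    "generate_spawn_points",
    "circular_position",
    "linear_position",
    "observed_angular_speed",
    "visual_angle",
    "velocity_table",
    "round_half_up",
]

# Geometry constants of the study conditions (metres, degrees).
SPHERE_RADIUS = 0.2
NEAR_DISTANCE = 0.4           # spawn-sphere centre, single-target setting
NEAR_DISTANCE_CROWDED = 0.8   # spawn-sphere centre, multi-object setting
FAR_DISTANCE = 1.4
CIRCULAR_SPEED_DEG = 45.0     # deg/s about the sphere centre
LINEAR_SPEED = 0.15           # m/s
TARGET_DIAMETER = 0.07        # m

PARALLEL_TOL = 1e-9

_LETTER_OFFSET = {
    "l": np.array([-1.0, 0.0, 0.0]),
    "r": np.array([1.0, 0.0, 0.0]),
    "t": np.array([0.0, 1.0, 0.0]),
    "b": np.array([0.0, -1.0, 0.0]),
    "n": np.array([0.0, 0.0, -1.0]),
    "f": np.array([0.0, 0.0, 1.0]),
}

_AXIS_VECTORS = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


def _cube_labels() -> list[str]:
    labels = []
    for xs, zs, ys in itertools.product(("l", "", "r"), ("n", "", "f"), ("t", "", "b")):
        lab = xs + zs + ys
        if lab:
            labels.append(lab)
    return labels


#: Canonical order of the 26 spawn-point labels.
SPAWN_LABELS: tuple[str, ...] = tuple(sorted(_cube_labels(), key=lambda s: (len(s), s)))

#: Default assignment of each spawn point to the principal rotation axis of its
#: circular trajectory.  The resulting seven circles each carry 2-6 points; the
#: equatorial circle about z collects exactly the lateral group lt,l,lb,b,rb,rt.
DEFAULT_TRAJECTORY_AXES: dict[str, str] = {
    # equator about the viewing axis + the eight corners (top/bottom rings)
    **{lab: "z" for lab in ("lt", "l", "lb", "b", "rb", "rt",
                            "lnt", "lnb", "lft", "lfb", "rnt", "rnb", "rft", "rfb")},
    # great circle(s) in the y-z plane
    **{lab: "x" for lab in ("t", "f", "n", "ft", "fb", "nt", "nb")},
    # great circle(s) in the x-z plane
    **{lab: "y" for lab in ("r", "rf", "rn", "ln", "lf")},
}


#: Reconstruction of the seven circular trajectories: each is an arc of a
#: circle about the member points' common rotation axis, carrying 2-6 spawn
#: points.  The equatorial group is exactly the lateral target group of the
#: published velocity table.
DEFAULT_TRAJECTORIES: dict[str, tuple[str, ...]] = {
    "equator": ("lt", "l", "lb", "b", "rb", "rt"),
    "corners-near": ("lnt", "rnt", "rnb", "lnb"),
    "corners-far": ("lft", "rft", "rfb", "lfb"),
    "vertical-far": ("t", "ft", "f", "fb"),
    "vertical-near": ("n", "nt", "nb"),
    "horizontal-right": ("r", "rf", "rn"),
    "horizontal-left": ("ln", "lf"),
}


class SphericalCoord(NamedTuple):
    """Observer-relative position: radius (m), pitch theta and yaw phi (deg)."""

    r: float
    theta: float
    phi: float


@dataclass(frozen=True)
class GazeRay:
    """A single eye's gaze: ray origin (eye position) and unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if origin.shape != (3,) or direction.shape != (3,):
            raise ValueError("origin and direction must be 3-vectors")
        if not (np.isfinite(origin).all() and np.isfinite(direction).all()):
            raise ValueError("ray components must be finite")
        n = np.linalg.norm(direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length (norm {n})")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)


def to_spherical(p) -> SphericalCoord:
    """Convert a Cartesian point to observer-relative spherical coordinates."""
    x, y, z = np.asarray(p, dtype=float)
    r = math.sqrt(x * x + y * y + z * z)
    if r == 0.0:
        return SphericalCoord(0.0, 0.0, 0.0)
    theta = math.degrees(math.asin(max(-1.0, min(1.0, y / r))))
    phi = math.degrees(math.atan2(x, z))
    if phi <= -180.0:
        phi = 180.0
    return SphericalCoord(r, theta, phi)


def to_cartesian(s: SphericalCoord) -> np.ndarray:
    """Inverse of :func:`to_spherical`."""
    r, theta, phi = float(s[0]), math.radians(s[1]), math.radians(s[2])
    y = r * math.sin(theta)
    rho = r * math.cos(theta)
    return np.array([rho * math.sin(phi), y, rho * math.cos(phi)])


def cart_to_sph(points: np.ndarray) -> np.ndarray:
    """Vectorised conversion of an ``(N, 3)`` array of xyz rows to (r, theta, phi)."""
    p = np.asarray(points, dtype=float)
    r = np.linalg.norm(p, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arcsin(np.clip(np.where(r > 0, p[..., 1] / np.where(r > 0, r, 1.0), 0.0), -1, 1)))
    phi = np.degrees(np.arctan2(p[..., 0], p[..., 2]))
    theta = np.where(r > 0, theta, 0.0)
    phi = np.where(r > 0, phi, 0.0)
    return np.stack([r, theta, phi], axis=-1)


def sph_to_cart(sph: np.ndarray) -> np.ndarray:
    """Vectorised inverse of :func:`cart_to_sph` for ``(N, 3)`` (r, theta, phi) rows."""
    s = np.asarray(sph, dtype=float)
    r = s[..., 0]
    theta = np.radians(s[..., 1])
    phi = np.radians(s[..., 2])
    y = r * np.sin(theta)
    rho = r * np.cos(theta)
    return np.stack([rho * np.sin(phi), y, rho * np.cos(phi)], axis=-1)


def unwrap_phi(phi_deg: np.ndarray) -> np.ndarray:
    """Remove +-360 deg jumps from a yaw sequence crossing the +-180 deg seam."""
    return np.unwrap(np.asarray(phi_deg, dtype=float), period=360.0)


# ---------------------------------------------------------------------------
# 3D point of regard
# ---------------------------------------------------------------------------

def compute_3d_por(left: GazeRay, right: GazeRay, parallel_tol: float = PARALLEL_TOL):
    """Binocular 3D point of regard.

    Returns the midpoint of the shortest segment between the two gaze lines
    (the intersection point if the lines intersect), or ``None`` when the rays
    are (near-)parallel -- the norm of the direction cross product falls below
    ``parallel_tol`` -- in which case the caller should treat the frame as an
    invalid sample.
    """
    por, valid = por_from_rays(
        left.origin[None], left.direction[None], right.origin[None], right.direction[None],
        parallel_tol=parallel_tol,
    )
    if not valid[0]:
        return None
    return por[0]


def por_from_rays(o1, d1, o2, d2, parallel_tol: float = PARALLEL_TOL):
    """Vectorised closest-approach midpoint of ray pairs.

    Parameters are ``(N, 3)`` arrays of origins and unit directions.  Returns
    ``(points, valid)`` where invalid (near-parallel) rows hold NaN.
    """
    o1 = np.asarray(o1, float)
    d1 = np.asarray(d1, float)
    o2 = np.asarray(o2, float)
    d2 = np.asarray(d2, float)
    w0 = o1 - o2
    b = np.sum(d1 * d2, axis=-1)
    d = np.sum(d1 * w0, axis=-1)
    e = np.sum(d2 * w0, axis=-1)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=-1)
    valid = cross_norm > parallel_tol
    denom = np.where(valid, 1.0 - b * b, 1.0)
    s = (b * e - d) / denom
    u = (e - b * d) / denom
    p1 = o1 + s[..., None] * d1
    p2 = o2 + u[..., None] * d2
    mid = 0.5 * (p1 + p2)
    mid = np.where(valid[..., None], mid, np.nan)
    return mid, valid


# ---------------------------------------------------------------------------
# Spawn layout and trajectories
# ---------------------------------------------------------------------------

@dataclass
class SpawnLayout:
    """The 26 labelled spawn points on a sphere centred on the viewing axis."""

    center_distance: float
    sphere_radius: float
    points: dict[str, np.ndarray] = field(repr=False)
    trajectory_axes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRAJECTORY_AXES), repr=False)

    @property
    def center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.center_distance])

    def __post_init__(self):
        if len(self.points) != 26:
            raise ValueError(f"layout must hold exactly 26 points, got {len(self.points)}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "center_distance": self.center_distance,
                "sphere_radius": self.sphere_radius,
                "points": {k: list(v) for k, v in self.points.items()},
                "trajectory_axes": self.trajectory_axes,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpawnLayout":
        d = json.loads(text)
        return cls(
            center_distance=d["center_distance"],
            sphere_radius=d["sphere_radius"],
            points={k: np.asarray(v, float) for k, v in d["points"].items()},
            trajectory_axes=dict(d.get("trajectory_axes", DEFAULT_TRAJECTORY_AXES)),
        )


def generate_spawn_points(center_distance: float, sphere_radius: float = SPHERE_RADIUS) -> SpawnLayout:
    """Project the 26 cube landmarks onto the spawn sphere.

    The enclosed cube shares its centre with the sphere at ``(0, 0,
    center_distance)``; the 8 corners, 12 edge midpoints and 6 face centres
    are projected radially onto the sphere surface.
    """
    if not center_distance > sphere_radius > 0:
        raise ValueError("require center_distance > sphere_radius > 0")
    center = np.array([0.0, 0.0, center_distance])
    points: dict[str, np.ndarray] = {}
    for lab in SPAWN_LABELS:
        offset = np.sum([_LETTER_OFFSET[c] for c in lab], axis=0)
        offset = offset / np.linalg.norm(offset) * sphere_radius
        points[lab] = center + offset
    return SpawnLayout(center_distance, sphere_radius, points)


def circular_position(layout: SpawnLayout, label: str, t, omega: float = CIRCULAR_SPEED_DEG,
                      axis: str | None = None) -> np.ndarray:
    """Position(s) of a circularly moving object ``t`` seconds after onset.

    The spawn point rotates about the principal axis assigned to its
    trajectory (``layout.trajectory_axes``), passing through the sphere
    centre, at ``omega`` deg/s.  ``t`` may be a scalar or an array; the result
    stays on the sphere surface.
    """
    axis = axis or layout.trajectory_axes[label]
    axis_vec = _AXIS_VECTORS[axis]
    offset = layout.points[label] - layout.center
    t = np.asarray(t, dtype=float)
    angles = np.radians(omega) * t
    rot = Rotation.from_rotvec(np.multiply.outer(angles, axis_vec))
    vectors = np.tile(offset, angles.shape + (1,)) if angles.ndim else offset
    return layout.center + rot.apply(vectors)


def linear_position(direction_point, t, v: float = LINEAR_SPEED, origin=None) -> np.ndarray:
    """Position(s) of a linearly moving object ``t`` seconds after onset.

    The object starts at ``origin`` and moves with speed ``v`` towards (and
    beyond) ``direction_point``.
    """
    if v <= 0:
        raise ValueError("speed must be positive")
    direction_point = np.asarray(direction_point, float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    u = direction_point - origin
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("direction point coincides with the origin")
    u = u / n
    t = np.asarray(t, dtype=float)
    return origin + np.multiply.outer(t * v, u)


# ---------------------------------------------------------------------------
# Observer-relative quantities
# ---------------------------------------------------------------------------

def observed_angular_speed(tangential_speed: float, axial_distance: float) -> float:
    """Angular speed (deg/s) of a target as seen by the observer.

    ``tangential_speed`` is the target's speed perpendicular to the viewing
    axis (m/s); ``axial_distance`` the z distance of the target (group).
    Motion purely along the viewing axis has zero tangential speed and hence
    0 deg/s.
    """
    if axial_distance <= 0:
        raise ValueError("axial distance must be positive")
    return math.degrees(tangential_speed / axial_distance)


def visual_angle(diameter: float, distance: float) -> float:
    """Visual angle (degrees) subtended by an object of given diameter."""
    if diameter <= 0 or distance <= 0:
        raise ValueError("diameter and distance must be positive")
    return math.degrees(2.0 * math.atan(diameter / (2.0 * distance)))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as used for reported velocities."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _distance_from_axis(point: np.ndarray, center: np.ndarray, axis: str) -> float:
    rel = point - center
    a = _AXIS_VECTORS[axis]
    return float(np.linalg.norm(rel - np.dot(rel, a) * a))


def velocity_table(near: float = NEAR_DISTANCE, far: float = FAR_DISTANCE,
                   sphere_radius: float = SPHERE_RADIUS,
                   circular_speed: float = CIRCULAR_SPEED_DEG,
                   linear_speed: float = LINEAR_SPEED) -> list[dict]:
    """Observer-relative angular velocity of each reported target group.

    Reproduces the published velocity overview from the geometry constants
    alone.  For circular motion the tangential speed at spawn is
    ``omega_rad * circle_radius`` (circle radius = distance of the spawn point
    from its trajectory axis) and the axial distance is the spawn point's z
    coordinate.  For linear motion the full object speed acts tangentially at
    the group's centre distance, except for pure-depth motion (f, n) which is
    0 deg/s.  Values are rounded to one decimal, half up.
    """
    rows: list[dict] = []
    omega_rad = math.radians(circular_speed)
    for dist_name, dist in (("Near", near), ("Far", far)):
        layout = generate_spawn_points(dist, sphere_radius)
        for targets, rep in (("rt, rb, b, lb, l, lt", "l"), ("f", "f"), ("n", "n")):
            p = layout.points[rep]
            radius = _distance_from_axis(p, layout.center, layout.trajectory_axes[rep])
            value = observed_angular_speed(omega_rad * radius, float(p[2]))
            rows.append({"movement": "Circular", "distance": dist_name,
                         "targets": targets, "deg_per_s": round_half_up(value)})
    for dist_name, dist in (("Near", near), ("Far", far)):
        layout = generate_spawn_points(dist, sphere_radius)
        for targets, rep in (("rt, rb, b, lb, l, lt, t, r", "l"), ("f, n", "f")):
            u = layout.points[rep] - layout.center
            lateral = math.hypot(u[0], u[1])
            tangential = 0.0 if lateral < 1e-12 else linear_speed
            value = observed_angular_speed(tangential, dist)
            rows.append({"movement": "Linear", "distance": dist_name,
                         "targets": targets, "deg_per_s": round_half_up(value)})
    return rows


def format_velocity_table(rows: Iterable[Mapping] | None = None) -> str:
    """Plain-text rendering of :func:`velocity_table`."""
    rows = list(rows) if rows is not None else velocity_table()
    lines = [f"{'Movement':<10}{'Distance':<10}{'Targets':<28}{'deg/s':>6}"]
    for r in rows:
        lines.append(f"{r['movement']:<10}{r['distance']:<10}{r['targets']:<28}{r['deg_per_s']:>6.1f}")
    return "\n".join(lines)
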