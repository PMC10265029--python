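"""Pose-dependent musculotendon path resolution with analytic wrapping.

Paths are ordered point sequences, each point fixed in a segment frame.
Between consecutive points the path is a straight line unless an assigned
wrap object (cylinder or sphere) obstructs it, in which case the shortest
surface-respecting route is substituted (obstacle-set method):

* sphere - two tangent segments joined by a great-circle arc in the plane
  containing both endpoints and the sphere centre;
* cylinder - the problem is projected perpendicular to the cylinder axis;
  the in-plane route is tangent-arc-tangent around the circle, and the
  axial coordinate varies linearly along the unrolled (developed) path, so
  the on-surface portion is a helix and the total length is
  ``hypot(planar_length, axial_travel)``.

Wrap engagement is hysteresis-free: a wrap is engaged iff the straight
candidate penetrates the surface, and at the tangency configuration the
wrapped and straight lengths agree, making path length continuous in pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelConfigError, PathResolutionError

logger = logging.getLogger(__name__)

MUSCLE_GROUPS = (
    "hip_flexor", "hip_extensor", "hip_abductor", "hip_adductor",
    "hip_internal_rotator", "hip_external_rotator",
    "knee_flexor", "knee_extensor",
    "ankle_dorsiflexor", "ankle_plantarflexor",
    "mtp_flexor", "mtp_extensor",
)

__all__ = [
    "MUSCLE_GROUPS",
    "WrapObject",
    "PathPoint",
    "MusculotendonUnit",
    "ResolvedPath",
    "resolve_path",
    "path_length",
]


@dataclass
class WrapObject:
    """Analytic wrapping obstacle fixed in one segment frame.

    ``frame`` is a 4x4 placement in the segment frame; the cylinder axis is
    the frame's local z. ``active_side`` restricts which way paths may wrap:
    one of '+x', '-x', '+y', '-y' interpreted as a half-space in the wrap
    frame that the contact arc must lie in; ``None`` picks the shorter arc.
    """

    name: str
    kind: str                       # 'cylinder' | 'sphere'
    segment: str
    radius: float
    half_length: float = 0.0        # cylinders only
    frame: np.ndarray = field(default_factory=lambda: np.eye(4))
    active_side: str | None = None

    def __post_init__(self):
        if self.kind not in ("cylinder", "sphere"):
            raise ModelConfigError(f"wrap {self.name}: unknown kind {self.kind!r}")
        if self.radius <= 0:
            raise ModelConfigError(f"wrap {self.name}: radius must be positive")
        if self.kind == "cylinder" and self.half_length <= 0:
            raise ModelConfigError(f"wrap {self.name}: half_length must be positive")
        if self.active_side not in (None, "+x", "-x", "+y", "-y"):
            raise ModelConfigError(f"wrap {self.name}: bad active_side")
        self.frame = np.asarray(self.frame, dtype=float).reshape(4, 4)

    def with_radius(self, radius: float) -> "WrapObject":
        return WrapObject(self.name, self.kind, self.segment, radius,
                          self.half_length, self.frame.copy(), self.active_side)


@dataclass
class PathPoint:
    point: np.ndarray               # in segment frame, m
    segment: str

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)


@dataclass
class MusculotendonUnit:
    """A path-bearing actuator: ordered fixed points plus wrap assignments.

    ``wraps`` maps wrap-object name -> gap indices it may act on (``None``
    means every gap). Functional-group labels come from ``MUSCLE_GROUPS``.
    """

    name: str
    points: list                    # list[PathPoint]
    wraps: dict = field(default_factory=dict)
    mass: float = 0.0
    groups: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 2:
            raise ModelConfigError(f"{self.name}: needs at least 2 path points")
        if self.points[0].segment == self.points[-1].segment:
            raise ModelConfigError(
                f"{self.name}: first and last points on the same segment")
        for g in self.groups:
            if g not in MUSCLE_GROUPS:
                raise ModelConfigError(f"{self.name}: unknown group {g!r}")

    def crosses(self, model, joint_name: str) -> bool:
        """True when the joint lies on the chain between the end segments."""
        joint = model.joints[joint_name]
        chain_first = {j.name for j in model.chain_to_root(self.points[0].segment)}
        chain_last = {j.name for j in model.chain_to_root(self.points[-1].segment)}
        return joint.name in (chain_first ^ chain_last)


@dataclass
class ResolvedPath:
    pose: object
    polyline: np.ndarray            # world-space, includes wrap contact arcs
    length: float
    engaged: dict                   # wrap name -> bool

    def __post_init__(self):
        self.polyline = np.asarray(self.polyline, dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# 2D circle wrap primitive
# ---------------------------------------------------------------------------

def _circle_wrap_2d(p, s, r, side_dir=None):
    """Shortest route from p to s around a circle of radius r at the origin.

    Both points must be outside the circle. Returns ``None`` when the
    straight segment clears the circle, else a dict with tangent lengths,
    tangent-point angles, signed wrap direction and arc angle.
    ``side_dir``: unit 2-vector; when given, the arc must lie in the
    half-plane ``dot(x, side_dir) > 0``.
    """
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    dp, ds = np.linalg.norm(p), np.linalg.norm(s)
    if dp <= r or ds <= r:
        raise PathResolutionError("path endpoint inside wrap surface")
    # closest approach of the segment to the origin
    seg = s - p
    denom = seg @ seg
    t = 0.0 if denom < 1e-30 else float(np.clip(-(p @ seg) / denom, 0.0, 1.0))
    closest = p + t * seg
    if np.linalg.norm(closest) >= r:
        return None  # straight segment clears the surface

    phi_p = np.arctan2(p[1], p[0])
    phi_s = np.arctan2(s[1], s[0])
    alpha_p = np.arccos(np.clip(r / dp, -1.0, 1.0))
    alpha_s = np.arccos(np.clip(r / ds, -1.0, 1.0))
    t_p = np.sqrt(max(dp * dp - r * r, 0.0))
    t_s = np.sqrt(max(ds * ds - r * r, 0.0))

    candidates = []
    for omega in (+1.0, -1.0):
        a_p = phi_p + omega * alpha_p      # contact angle leaving p
        a_s = phi_s - omega * alpha_s      # contact angle arriving at s
        arc = (omega * (a_s - a_p)) % (2.0 * np.pi)
        if side_dir is not None:
            # the entire contact arc must lie in the active half-plane
            angs = _sample_arc(r, a_p, omega, arc)
            arc_pts = np.column_stack([np.cos(angs), np.sin(angs)])
            if np.min(arc_pts @ side_dir) < -1e-12:
                continue
        candidates.append({
            "omega": omega, "a_p": a_p, "a_s": a_s, "arc": arc,
            "t_p": t_p, "t_s": t_s,
            "planar_length": t_p + r * arc + t_s,
        })
    if not candidates:
        raise PathResolutionError(
            "no feasible tangent respecting the wrap side constraint")
    if side_dir is None and len(candidates) == 2:
        logger.debug("wrap side unset: taking shorter of the two arcs")
    return min(candidates, key=lambda c: c["planar_length"])


def _sample_arc(r, a_start, omega, arc, step=np.deg2rad(5.0)):
    """Angles along the contact arc, inclusive of both ends."""
    n = max(int(np.ceil(arc / step)), 1)
    return a_start + omega * arc * np.linspace(0.0, 1.0, n + 1)


# ---------------------------------------------------------------------------
# single-gap wrapping
# ---------------------------------------------------------------------------

def _wrap_gap_cylinder(p_w, s_w, wrap: WrapObject, wrap_to_world: np.ndarray):
    """Route p->s (world) around a cylinder. Returns (points, length) or None."""
    world_to_wrap = np.linalg.inv(wrap_to_world)
    p = world_to_wrap[:3, :3] @ p_w + world_to_wrap[:3, 3]
    s = world_to_wrap[:3, :3] @ s_w + world_to_wrap[:3, 3]
    side = _side_vector(wrap.active_side)
    sol = _circle_wrap_2d(p[:2], s[:2], wrap.radius, side)
    if sol is None:
        return None
    planar = sol["planar_length"]
    dz = s[2] - p[2]
    length = float(np.hypot(planar, dz))
    # z varies linearly with unrolled planar arc-length
    angles = _sample_arc(wrap.radius, sol["a_p"], sol["omega"], sol["arc"])
    u = sol["t_p"] + wrap.radius * np.abs(angles - sol["a_p"])
    zs = p[2] + dz * u / planar if planar > 0 else np.full_like(u, p[2])
    arc_pts = np.column_stack([wrap.radius * np.cos(angles),
                               wrap.radius * np.sin(angles), zs])
    if wrap.half_length and np.any(np.abs(zs) > wrap.half_length + 1e-9):
        logger.warning("wrap %s: contact helix exceeds cylinder half-length",
                       wrap.name)
    local = np.vstack([p, arc_pts, s])
    world = local @ wrap_to_world[:3, :3].T + wrap_to_world[:3, 3]
    return world[1:-1], length


def _wrap_gap_sphere(p_w, s_w, wrap: WrapObject, wrap_to_world: np.ndarray):
    """Route p->s (world) around a sphere. Returns (points, length) or None."""
    centre = wrap_to_world[:3, 3]
    p = p_w - centre
    s = s_w - centre
    dp, ds = np.linalg.norm(p), np.linalg.norm(s)
    if dp <= wrap.radius or ds <= wrap.radius:
        raise PathResolutionError("path endpoint inside wrap surface")
    # closest approach of the 3D chord to the centre
    seg = s - p
    denom = seg @ seg
    t = 0.0 if denom < 1e-30 else float(np.clip(-(p @ seg) / denom, 0.0, 1.0))
    if np.linalg.norm(p + t * seg) >= wrap.radius:
        return None
    # reduce to 2D in the plane spanned by p and s through the centre
    e1 = p / dp
    s_perp = s - (s @ e1) * e1
    n_perp = np.linalg.norm(s_perp)
    if n_perp < 1e-12:  # endpoints collinear with centre: bend plane degenerate
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
    else:
        e2 = s_perp / n_perp
    p2 = np.array([dp, 0.0])
    s2 = np.array([s @ e1, s @ e2])
    sol = _circle_wrap_2d(p2, s2, wrap.radius)
    if sol is None:
        return None
    angles = _sample_arc(wrap.radius, sol["a_p"], sol["omega"], sol["arc"])
    arc2 = wrap.radius * np.column_stack([np.cos(angles), np.sin(angles)])
    world = centre + np.outer(arc2[:, 0], e1) + np.outer(arc2[:, 1], e2)
    return world, float(sol["planar_length"])


def _side_vector(active_side):
    if active_side is None:
        return None
    sign = +1.0 if active_side[0] == "+" else -1.0
    return sign * (np.array([1.0, 0.0]) if active_side[1] == "x"
                   else np.array([0.0, 1.0]))


# ---------------------------------------------------------------------------
# full path resolution
# ---------------------------------------------------------------------------

def resolve_path(mtu: MusculotendonUnit, model, pose,
                 wrap_objects: dict | None = None) -> ResolvedPath:
    """World-space path of an MTU at a pose, honouring via points and wraps.

    ``wrap_objects`` maps name -> :class:`WrapObject`; required when the MTU
    has wrap assignments. Multiple wraps assigned to one gap are tried in
    declaration order; the first engaged wrap routes the gap (documented
    single-obstacle limitation).
    """
    wrap_objects = wrap_objects or {}
    for wname in mtu.wraps:
        if wname not in wrap_objects:
            raise ModelConfigError(
                f"{mtu.name}: wrap assignment {wname!r} not declared")

    world_pts = [model.point_to_world(pose, pp.segment, pp.point)
                 for pp in mtu.points]
    wrap_frames = {
        name: model.segment_to_world(pose, w.segment) @ w.frame
        for name, w in wrap_objects.items()}

    polyline = [world_pts[0]]
    total = 0.0
    engaged = {name: False for name in mtu.wraps}
    for gap, (p, s) in enumerate(zip(world_pts[:-1], world_pts[1:])):
        routed = None
        for wname, gaps in mtu.wraps.items():
            if gaps is not None and gap not in gaps:
                continue
            w = wrap_objects[wname]
            try:
                if w.kind == "cylinder":
                    routed = _wrap_gap_cylinder(p, s, w, wrap_frames[wname])
                else:
                    routed = _wrap_gap_sphere(p, s, w, wrap_frames[wname])
            except PathResolutionError as exc:
                raise PathResolutionError(
                    f"{mtu.name}, gap {gap}, wrap {wname}: {exc}") from exc
            if routed is not None:
                engaged[wname] = True
                break
        if routed is None:
            total += float(np.linalg.norm(s - p))
        else:
            contact, length = routed
            total += length
            polyline.extend(contact)
        polyline.append(s)
    return ResolvedPath(pose=pose, polyline=np.asarray(polyline),
                        length=total, engaged=engaged)


def path_length(mtu: MusculotendonUnit, model, pose,
                wrap_objects: dict | None = None) -> float:
    """Total musculotendon path length (m) at a pose."""
    return resolve_path(mtu, model, pose, wrap_objects).length
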