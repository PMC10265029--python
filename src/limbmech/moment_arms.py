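"""Tendon-excursion moment arms and group-summed peak-normalized curves.

The moment arm of a musculotendon unit about a joint coordinate is the
perpendicular-distance leverage of its line of action about the joint axis,
obtained here as the tendon excursion r(theta) = -dL/dtheta (length in
metres, angle in radians): a muscle that shortens as the coordinate
increases has a positive arm and drives that rotation.

Group curves sum the member arms (oriented so the group's action is
positive) and divide by the sum of the members' peak arms, so a group peaks
at 1 only where every member peaks simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import LimbmechError, PathResolutionError
from .path_engine import path_length

logger = logging.getLogger(__name__)

__all__ = [
    "MomentArmCurve",
    "GroupCurve",
    "moment_arm_curve",
    "straight_line_moment_arm",
    "classify_function",
    "group_summed_normalized",
]

# anatomical label pairs (positive-sign label, negative-sign label) per axis
_AXIS_LABELS = {
    "Z": ("flexor", "extensor"),
    "X": ("abductor", "adductor"),
    "Y": ("internal_rotator", "external_rotator"),
}


@dataclass
class MomentArmCurve:
    muscle: str
    joint: str
    dof: str
    angles_deg: np.ndarray
    values_m: np.ndarray
    continuity_threshold: float = 0.02  # m per sample; jump guard

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.values_m = np.asarray(self.values_m, dtype=float)
        if len(self.angles_deg) < 11:
            raise LimbmechError("moment-arm grid needs at least 11 samples")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise LimbmechError("angle grid must be strictly increasing")
        if not np.all(np.isfinite(self.values_m)):
            raise LimbmechError(f"{self.muscle}: non-finite moment arm")
        jumps = np.abs(np.diff(self.values_m))
        if jumps.size and jumps.max() > self.continuity_threshold:
            logger.warning("%s %s/%s: moment-arm jump %.4f m between samples",
                           self.muscle, self.joint, self.dof, jumps.max())

    def scaled(self, factor: float) -> "MomentArmCurve":
        return MomentArmCurve(self.muscle, self.joint, self.dof,
                              self.angles_deg.copy(), self.values_m * factor,
                              self.continuity_threshold)


@dataclass
class GroupCurve:
    group: str
    joint: str
    dof: str
    angles_deg: np.ndarray
    normalized: np.ndarray
    muscles: list = field(default_factory=list)
    peak_sum_m: float = 0.0

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if self.normalized.max() > 1.0 + 1e-9:
            raise LimbmechError(
                f"group {self.group}: normalized curve exceeds 1")


def moment_arm_curve(mtu, model, joint: str, dof: str, angles_deg,
                     wrap_objects=None, step_deg: float = 0.5,
                     base_pose=None) -> MomentArmCurve:
    """Tendon-excursion moment arm over an angle grid (degrees).

    Finite differences with ``step_deg``: fourth-order central stencils in
    the grid interior and one-sided stencils of matching order at the grid
    ends (so end samples never require poses outside the grid). The
    derivative is taken with respect to the angle in radians so values are
    metres. ``base_pose`` fixes the other coordinates (default neutral).
    """
    from .skeleton import Pose

    if joint not in model.joints:
        raise LimbmechError(f"unknown joint {joint!r}")
    model.joints[joint].dof(dof)  # validates dof
    if not mtu.crosses(model, joint):
        raise LimbmechError(f"{mtu.name} does not cross joint {joint!r}")
    angles = np.asarray(angles_deg, dtype=float)
    lo, hi = angles.min(), angles.max()
    h = np.deg2rad(step_deg)
    pose0 = base_pose if base_pose is not None else Pose.neutral()

    def L(theta_deg: float) -> float:
        pose = pose0.with_angle(joint, dof, theta_deg)
        try:
            return path_length(mtu, model, pose, wrap_objects)
        except PathResolutionError as exc:
            raise PathResolutionError(
                f"{mtu.name}: path failed at {joint}/{dof}={theta_deg:g} deg: {exc}"
            ) from exc

    # fourth-order stencils (coefficients / 12h)
    central = ((-2, 1.0), (-1, -8.0), (1, 8.0), (2, -1.0))
    forward = ((0, -25.0), (1, 48.0), (2, -36.0), (3, 16.0), (4, -3.0))
    values = np.empty_like(angles)
    for i, th in enumerate(angles):
        if th - 2 * step_deg >= lo and th + 2 * step_deg <= hi:
            stencil = central
        elif th - 2 * step_deg < lo:
            stencil = forward
        else:
            stencil = tuple((-k, -c) for k, c in forward)
        dL = sum(c * L(th + k * step_deg) for k, c in stencil)
        values[i] = -dL / (12.0 * h)
    return MomentArmCurve(mtu.name, joint, dof, angles, values)


def straight_line_moment_arm(origin_world, insertion_world, axis_point,
                             axis_dir) -> float:
    """Geometric moment arm of a straight line of action about an axis.

    r = p_hat . (omega_hat x q), where p_hat is the pull direction at the
    moment-bearing point (insertion -> origin) and q the moment-bearing
    point relative to a point on the axis: per unit tension, the moment the
    muscle generates about the axis. Used as the independent oracle for the
    tendon-excursion computation (r = -dL/dtheta).
    """
    o = np.asarray(origin_world, dtype=float)
    i = np.asarray(insertion_world, dtype=float)
    w = np.asarray(axis_dir, dtype=float)
    w = w / np.linalg.norm(w)
    p = o - i
    p = p / np.linalg.norm(p)
    q = i - np.asarray(axis_point, dtype=float)
    return float(p @ np.cross(w, q))


def classify_function(curve: MomentArmCurve, sign_convention: float = 1.0):
    """Anatomical label from the dominant sign of the arm over the ROM.

    ``sign_convention`` is the joint DOF's sign (+1/-1) mapping rotation
    direction to the anatomical positive action. Returns
    ``(label, switches_function)``; an all-zero curve maps to 'no function'.
    """
    v = curve.values_m * sign_convention
    if np.allclose(v, 0.0, atol=1e-12):
        return "no function", False
    pos_label, neg_label = _AXIS_LABELS[curve.dof]
    mean = float(v.mean())
    label = pos_label if mean >= 0 else neg_label
    switches = bool(v.max() > 1e-12 and v.min() < -1e-12)
    return label, switches


def group_summed_normalized(curves, group: str, sign: float = 1.0,
                            use_abs: bool = False) -> GroupCurve:
    """Sum member arms and normalize by the sum of the members' peaks.

    ``sign`` orients the curves so the group's action is positive (e.g. -1
    for an extensor group at a joint whose flexion is positive); with
    ``use_abs`` the absolute arms are summed instead (for muscles that
    switch function mid-ROM).
    """
    curves = list(curves)
    if not curves:
        raise LimbmechError("empty muscle group")
    grid = curves[0].angles_deg
    joint, dof = curves[0].joint, curves[0].dof
    for c in curves[1:]:
        if c.joint != joint or c.dof != dof or not np.array_equal(c.angles_deg, grid):
            raise LimbmechError("group curves must share joint, dof and grid")
    oriented = np.array([np.abs(c.values_m) if use_abs else sign * c.values_m
                         for c in curves])
    peaks = oriented.max(axis=1)
    denom = float(peaks.sum())
    if denom <= 0:
        raise LimbmechError(f"group {group}: zero summed peak moment arm")
    normalized = oriented.sum(axis=0) / denom
    return GroupCurve(group=group, joint=joint, dof=dof,
                      angles_deg=grid.copy(), normalized=normalized,
                      muscles=[c.muscle for c in curves], peak_sum_m=denom)
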