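"""Kinematic model: segments, joint coordinate systems, poses, osteometrics.

Conventions
-----------
* Segment graph is a tree rooted at the pelvis; the pelvis (root) frame is
  the world frame, with its origin at the centre of the pelvis.
* Each joint carries an orthonormal right-handed axis triad expressed in the
  parent segment frame: X = abduction/adduction, Y = long-axis rotation,
  Z = flexion-extension.
* At the neutral pose (all angles zero) every child frame coincides with its
  parent frame up to the joint-location translation.
* Rotations within a joint compose intrinsically in the order Z (flexion-
  extension), then X, then Y. Angles are degrees in all public interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, ModelConfigError
from .mesh_core import TriMesh, fit_sphere

logger = logging.getLogger(__name__)

ROTATION_ORDER = ("Z", "X", "Y")

__all__ = [
    "DofSpec",
    "JointCoordinateSystem",
    "Segment",
    "Pose",
    "KinematicModel",
    "build_model",
    "measure_biacetabular_diameter",
    "measure_subpubic_angle",
]


@dataclass
class DofSpec:
    """One rotational degree of freedom: axis label, range of motion, sign.

    ``sign`` maps the anatomical angle convention onto the right-hand-rule
    rotation about the axis (e.g. knee flexion negative).
    """

    axis: str                      # 'X' | 'Y' | 'Z'
    rom: tuple = (-180.0, 180.0)   # degrees, min < max
    sign: float = 1.0

    def __post_init__(self):
        if self.axis not in ("X", "Y", "Z"):
            raise ModelConfigError(f"unknown DOF axis {self.axis!r}")
        lo, hi = self.rom
        if not lo < hi:
            raise ModelConfigError(f"ROM min must be < max, got {self.rom}")
        if self.sign not in (-1.0, 1.0):
            raise ModelConfigError("DOF sign must be +1 or -1")


@dataclass
class JointCoordinateSystem:
    name: str
    parent_segment: str
    child_segment: str
    location: np.ndarray               # joint centre in parent frame, m
    axes: np.ndarray                   # 3x3, columns = X, Y, Z in parent frame
    dofs: list = field(default_factory=list)

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.abs(self.axes.T @ self.axes - np.eye(3)).max() > 1e-9:
            raise ModelConfigError(f"joint {self.name}: axes not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ModelConfigError(f"joint {self.name}: axes not right-handed")
        labels = [d.axis for d in self.dofs]
        if len(set(labels)) != len(labels):
            raise ModelConfigError(f"joint {self.name}: duplicate DOF axes")

    def dof(self, axis: str) -> DofSpec:
        for d in self.dofs:
            if d.axis == axis:
                return d
        raise ModelConfigError(f"joint {self.name} has no {axis} DOF")

    def rotation(self, angles_deg: dict) -> np.ndarray:
        """3x3 rotation of the child frame in the parent frame.

        ``angles_deg`` maps axis label -> anatomical angle in degrees; axes
        without a configured DOF must stay at zero.
        """
        by_axis = {"X": 0.0, "Y": 0.0, "Z": 0.0}
        for axis, ang in angles_deg.items():
            self.dof(axis)  # raises for a non-existent DOF
            by_axis[axis] = float(ang) * self.dof(axis).sign
        R = np.eye(3)
        for axis in ROTATION_ORDER:
            R = R @ _axis_rotation(axis, np.deg2rad(by_axis[axis]))
        return self.axes @ R @ self.axes.T

    def transform(self, angles_deg: dict) -> np.ndarray:
        """4x4 transform mapping child-frame points to the parent frame."""
        T = np.eye(4)
        T[:3, :3] = self.rotation(angles_deg)
        T[:3, 3] = self.location
        return T


def _axis_rotation(axis: str, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    if axis == "X":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "Y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class Segment:
    name: str
    parent: str | None = None
    meshes: list = field(default_factory=list)   # list[TriMesh], segment frame
    mass: float = 0.0
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        if self.mass < 0:
            raise ModelConfigError(f"segment {self.name}: negative mass")
        if np.abs(self.inertia - self.inertia.T).max() > 1e-9:
            raise ModelConfigError(f"segment {self.name}: inertia not symmetric")


class Pose(dict):
    """Mapping joint name -> {axis label -> angle degrees}.

    The neutral pose is the empty mapping (all angles zero).
    """

    @classmethod
    def neutral(cls) -> "Pose":
        return cls()

    def angle(self, joint: str, axis: str) -> float:
        return float(self.get(joint, {}).get(axis, 0.0))

    def with_angle(self, joint: str, axis: str, value: float) -> "Pose":
        new = Pose({k: dict(v) for k, v in self.items()})
        new.setdefault(joint, {})[axis] = float(value)
        return new


class KinematicModel:
    """Validated segment tree + joints; computes world transforms per pose."""

    def __init__(self, segments: list, joints: list, name: str = "model"):
        self.name = name
        self.segments = {s.name: s for s in segments}
        self.joints = {j.name: j for j in joints}
        if len(self.segments) != len(segments):
            raise ModelConfigError("duplicate segment names")
        self._joint_by_child = {}
        for j in joints:
            for seg in (j.parent_segment, j.child_segment):
                if seg not in self.segments:
                    raise ModelConfigError(
                        f"joint {j.name} references unknown segment {seg!r}")
            if j.child_segment in self._joint_by_child:
                raise ModelConfigError(
                    f"segment {j.child_segment} has more than one parent joint")
            self._joint_by_child[j.child_segment] = j
        roots = [s.name for s in segments if s.name not in self._joint_by_child]
        if len(roots) != 1:
            raise ModelConfigError(f"segment graph must have one root, found {roots}")
        self.root = roots[0]
        # cycle check: walk up from every segment
        for name in self.segments:
            seen = set()
            cur = name
            while cur != self.root:
                if cur in seen:
                    raise ModelConfigError(f"cycle in segment graph at {cur}")
                seen.add(cur)
                cur = self._joint_by_child[cur].parent_segment

    @property
    def n_dofs(self) -> int:
        return sum(len(j.dofs) for j in self.joints.values())

    def parent_joint(self, segment: str):
        return self._joint_by_child.get(segment)

    def chain_to_root(self, segment: str) -> list:
        """Joints from the root down to ``segment``, proximal first."""
        chain = []
        cur = segment
        while cur != self.root:
            j = self._joint_by_child[cur]
            chain.append(j)
            cur = j.parent_segment
        return chain[::-1]

    def validate_pose(self, pose: Pose, clamp: bool = False) -> Pose:
        """Reject (or clamp, with a warning) angles outside the ROM."""
        out = Pose()
        for jname, angles in pose.items():
            if jname not in self.joints:
                raise ModelConfigError(f"pose references unknown joint {jname!r}")
            joint = self.joints[jname]
            for axis, ang in angles.items():
                lo, hi = joint.dof(axis).rom
                if not lo <= ang <= hi:
                    if clamp:
                        clamped = min(max(ang, lo), hi)
                        logger.warning("%s/%s: %g deg clamped to [%g, %g]",
                                       jname, axis, ang, lo, hi)
                        ang = clamped
                    else:
                        raise ModelConfigError(
                            f"{jname}/{axis}: angle {ang} outside ROM [{lo}, {hi}]")
                out.setdefault(jname, {})[axis] = float(ang)
        return out

    def segment_to_world(self, pose: Pose, segment: str) -> np.ndarray:
        """4x4 transform from the segment frame to the world (root) frame."""
        if segment not in self.segments:
            raise ModelConfigError(f"unknown segment {segment!r}")
        T = np.eye(4)
        for joint in self.chain_to_root(segment):
            T = T @ joint.transform(pose.get(joint.name, {}))
        return T

    def point_to_world(self, pose: Pose, segment: str, point) -> np.ndarray:
        T = self.segment_to_world(pose, segment)
        return T[:3, :3] @ np.asarray(point, dtype=float) + T[:3, 3]


def build_model(config: dict) -> KinematicModel:
    """Assemble and validate a model from a parsed configuration mapping.

    See :mod:`limbmech.io_model` for the YAML schema and round-tripping.
    """
    segments = []
    for s in config.get("segments", []):
        segments.append(Segment(
            name=s["name"],
            parent=s.get("parent"),
            mass=float(s.get("mass", 0.0)),
            com=np.asarray(s.get("com", [0, 0, 0]), dtype=float),
            inertia=np.asarray(s.get("inertia", np.zeros((3, 3))), dtype=float),
        ))
    joints = []
    for j in config.get("joints", []):
        axes = j.get("axes")
        if axes is None:
            axes_mat = np.eye(3)
        elif isinstance(axes, dict):
            axes_mat = np.column_stack([
                np.asarray(axes[k], dtype=float) for k in ("x", "y", "z")])
        else:
            axes_mat = np.asarray(axes, dtype=float).reshape(3, 3)
        dofs = [DofSpec(axis=d["axis"],
                        rom=tuple(d.get("rom", (-180.0, 180.0))),
                        sign=float(d.get("sign", 1.0)))
                for d in j.get("dofs", [])]
        joints.append(JointCoordinateSystem(
            name=j["name"], parent_segment=j["parent"], child_segment=j["child"],
            location=np.asarray(j.get("location", [0, 0, 0]), dtype=float),
            axes=axes_mat, dofs=dofs))
    return KinematicModel(segments, joints, name=config.get("name", "model"))


# ---------------------------------------------------------------------------
# osteometrics
# ---------------------------------------------------------------------------

def measure_biacetabular_diameter(left_points, right_points) -> float:
    """Distance between sphere centres fitted to the two acetabular cups.

    Returned in the units of the input point coordinates (customarily mm for
    osteometric point picks).
    """
    cl, _, _ = fit_sphere(left_points)
    cr, _, _ = fit_sphere(right_points)
    return float(np.linalg.norm(cl - cr))


def measure_subpubic_angle(left_line, right_line) -> float:
    """Angle (degrees) between the two inferior pubic rami.

    Each ramus is a pair of landmarks ``(subpubic_point, distal_point)``.
    Directions are projected onto the coronal plane (the anteroposterior
    coordinate, index 2 by this package's axis convention, is dropped)
    before the angle is measured. A zero angle (parallel rami) is returned
    as 0.0 and logged as a limit case.
    """
    def direction(line):
        a, b = (np.asarray(p, dtype=float) for p in line)
        d = b - a
        d2 = d[:2]  # coronal-plane projection: mediolateral, proximodistal
        n = np.linalg.norm(d2)
        if n < 1e-12:
            raise DegenerateGeometryError(
                "ramus landmarks coincide in the coronal projection")
        return d2 / n

    dl, dr = direction(left_line), direction(right_line)
    ang = float(np.degrees(np.arccos(np.clip(dl @ dr, -1.0, 1.0))))
    if ang < 1e-9:
        logger.warning("subpubic angle limit case: rami parallel (0 deg)")
    return ang
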