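"""Deterministic synthetic limbs, bellies and muscles with analytic oracles.

Every generator attaches its closed-form expected values (volumes, moment
arms, engagement ranges) as metadata so each pipeline stage can be tested
against an independent analytic result without any external data. Default
dimensions are hominin-limb scale (thigh 0.25 m, shank 0.22 m) so test
tolerances transfer to real use; geometry is exact unless seeded vertex
noise is explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_core import AttachmentPatch, TriMesh
from .muscle import PolygonalMuscle
from .path_engine import MusculotendonUnit, PathPoint, WrapObject
from .moment_arms import MomentArmCurve
from .skeleton import build_model

__all__ = [
    "SyntheticLimbSpec",
    "make_two_segment_limb",
    "make_hinge_limb",
    "make_spindle_muscle",
    "make_wrapped_muscle",
    "make_group_fixture",
    "make_box_mesh",
    "make_tube_mesh",
]


@dataclass
class SyntheticLimbSpec:
    thigh_length: float = 0.25
    shank_length: float = 0.22
    bone_radius: float = 0.015
    pelvis_size: tuple = (0.20, 0.10, 0.12)
    resolution: int = 32           # azimuthal divisions for rod meshes
    noise: float = 0.0             # vertex jitter std dev, m (opt-in)
    seed: int = 0

    def __post_init__(self):
        for v in (self.thigh_length, self.shank_length, self.bone_radius,
                  *self.pelvis_size):
            if v <= 0:
                raise ValueError("all synthetic dimensions must be positive")
        if self.resolution < 3:
            raise ValueError("resolution must be >= 3 azimuthal divisions")


# ---------------------------------------------------------------------------
# primitive meshes
# ---------------------------------------------------------------------------

def make_box_mesh(extents, center=(0.0, 0.0, 0.0), name="box") -> TriMesh:
    tm = trimesh.creation.box(extents=extents)
    tm.apply_translation(center)
    return TriMesh.from_trimesh(tm, name=name)


def make_tube_mesh(radius, length, resolution=32, name="tube") -> TriMesh:
    """Closed cylinder along -y from the origin (a limb 'bone' rod)."""
    tm = trimesh.creation.cylinder(radius=radius, height=length,
                                   sections=resolution)
    # trimesh builds along z centred at origin; move to [-length, 0] on y
    tm.apply_transform(trimesh.transformations.rotation_matrix(
        np.pi / 2.0, [1, 0, 0]))
    tm.apply_translation([0.0, -length / 2.0, 0.0])
    return TriMesh.from_trimesh(tm, name=name)


def _jitter(mesh: TriMesh, noise: float, rng) -> TriMesh:
    if noise <= 0:
        return mesh
    mesh = mesh.copy()
    mesh.vertices = mesh.vertices + rng.normal(0.0, noise, mesh.vertices.shape)
    return mesh


# ---------------------------------------------------------------------------
# limbs
# ---------------------------------------------------------------------------

def make_two_segment_limb(spec: SyntheticLimbSpec | None = None):
    """Pelvis block + thigh rod (3-DOF ball 'hip') + shank rod (Z-hinge 'knee').

    Segments hang along -y in the neutral pose. Returns ``(config, meshes)``
    where ``config`` builds a validated model via :func:`build_model` and
    ``meshes`` maps segment name -> TriMesh in that segment's frame.
    """
    spec = spec or SyntheticLimbSpec()
    rng = np.random.default_rng(spec.seed)
    meshes = {
        "pelvis": _jitter(make_box_mesh(spec.pelvis_size, name="pelvis"),
                          spec.noise, rng),
        "thigh": _jitter(make_tube_mesh(spec.bone_radius, spec.thigh_length,
                                        spec.resolution, name="thigh"),
                         spec.noise, rng),
        "shank": _jitter(make_tube_mesh(spec.bone_radius, spec.shank_length,
                                        spec.resolution, name="shank"),
                         spec.noise, rng),
    }
    config = {
        "name": "synthetic_two_segment_limb",
        "segments": [
            {"name": "pelvis", "parent": None},
            {"name": "thigh", "parent": "pelvis"},
            {"name": "shank", "parent": "thigh"},
        ],
        "joints": [
            {"name": "hip", "parent": "pelvis", "child": "thigh",
             "location": [0.0, 0.0, 0.0],
             "dofs": [
                 {"axis": "Z", "rom": [-60.0, 120.0], "sign": 1},
                 {"axis": "X", "rom": [-50.0, 50.0], "sign": 1},
                 {"axis": "Y", "rom": [-45.0, 45.0], "sign": 1},
             ]},
            {"name": "knee", "parent": "thigh", "child": "shank",
             "location": [0.0, -spec.thigh_length, 0.0],
             "dofs": [{"axis": "Z", "rom": [-120.0, 10.0], "sign": -1}]},
        ],
    }
    return config, meshes


def make_hinge_limb(length: float = 0.25, rom=(-90.0, 90.0)):
    """Minimal 1-DOF variant: base + arm with a single Z hinge at the origin."""
    config = {
        "name": "synthetic_hinge",
        "segments": [
            {"name": "base", "parent": None},
            {"name": "arm", "parent": "base"},
        ],
        "joints": [
            {"name": "hinge", "parent": "base", "child": "arm",
             "location": [0.0, 0.0, 0.0],
             "dofs": [{"axis": "Z", "rom": list(rom), "sign": 1}]},
        ],
    }
    return build_model(config)


# ---------------------------------------------------------------------------
# bellies
# ---------------------------------------------------------------------------

def make_spindle_muscle(r0: float = 0.02, length: float = 0.3,
                        resolution: int = 64, n_rings: int | None = None,
                        name: str = "spindle",
                        origin_segment: str = "pelvis",
                        insertion_segment: str = "thigh") -> PolygonalMuscle:
    """Fusiform belly of revolution about z with radius r(z) = r0 sin(pi z/L).

    The tips close to points, which serve as origin (z=0) and insertion
    (z=L) patches (the triangle fans around each tip vertex). The analytic
    enclosed volume, ``pi r0^2 L / 2``, is stored as
    ``muscle.analytic_volume``.
    """
    if r0 <= 0 or length <= 0:
        raise ValueError("r0 and length must be positive")
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    n_rings = n_rings or resolution
    zs = np.linspace(0.0, length, n_rings + 2)[1:-1]
    radii = r0 * np.sin(np.pi * zs / length)
    phis = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)

    verts = [np.array([0.0, 0.0, 0.0])]                   # bottom tip = 0
    for z, r in zip(zs, radii):
        for phi in phis:
            verts.append(np.array([r * np.cos(phi), r * np.sin(phi), z]))
    verts.append(np.array([0.0, 0.0, length]))            # top tip = last
    verts = np.asarray(verts)
    top = len(verts) - 1

    def ring(i, k):
        return 1 + i * resolution + (k % resolution)

    faces = []
    for k in range(resolution):                           # bottom fan (outward: -z)
        faces.append([0, ring(0, k + 1), ring(0, k)])
    for i in range(n_rings - 1):                          # side quads
        for k in range(resolution):
            a, b = ring(i, k), ring(i, k + 1)
            c, d = ring(i + 1, k + 1), ring(i + 1, k)
            faces.append([a, b, c])
            faces.append([a, c, d])
    for k in range(resolution):                           # top fan (outward: +z)
        faces.append([top, ring(n_rings - 1, k), ring(n_rings - 1, k + 1)])
    belly = TriMesh(verts, np.asarray(faces), name=name)

    faces_arr = np.asarray(faces)
    origin_ids = np.flatnonzero((faces_arr == 0).any(axis=1))
    insertion_ids = np.flatnonzero((faces_arr == top).any(axis=1))
    muscle = PolygonalMuscle(
        name=name, belly=belly,
        origin=AttachmentPatch(belly, origin_ids, segment=origin_segment),
        insertion=AttachmentPatch(belly, insertion_ids, segment=insertion_segment))
    muscle.analytic_volume = np.pi * r0 ** 2 * length / 2.0
    return muscle


# ---------------------------------------------------------------------------
# wrapped-muscle oracle
# ---------------------------------------------------------------------------

def make_wrapped_muscle(radius: float = 0.03, offsets=(-0.1, 0.1),
                        half_length: float = 0.1, active_side: str = "-y"):
    """Muscle spanning a Z-hinge with a coaxial wrap cylinder at the joint.

    The parent-fixed point sits at ``(offsets[0], 0, 0)`` on 'base', the
    child-fixed point at ``(offsets[1], 0, 0)`` on 'arm'. While the path
    wraps the cylinder, the tendon-excursion moment arm equals the cylinder
    radius exactly (the contact arc subtends the joint rotation one-to-one).

    Returns ``(model, mtu, wrap_objects)``; ``mtu.analytic_arm`` holds the
    radius and ``mtu.engagement_range_deg`` the hinge-angle interval over
    which the straight chord would penetrate the cylinder at build geometry.
    """
    p_off, s_off = offsets
    for off in offsets:
        if abs(off) <= radius:
            raise ValueError("attachment clearance must exceed the wrap radius")
    model = make_hinge_limb(rom=(-170.0, 170.0))
    mtu = MusculotendonUnit(
        name="wrapped_oracle",
        points=[PathPoint([p_off, 0.0, 0.0], "base"),
                PathPoint([s_off, 0.0, 0.0], "arm")],
        wraps={"joint_cylinder": None})
    wraps = {"joint_cylinder": WrapObject(
        name="joint_cylinder", kind="cylinder", segment="base",
        radius=radius, half_length=half_length, active_side=active_side)}
    mtu.analytic_arm = radius

    # engagement: hinge angle range where the rotating chord cuts the circle
    thetas = np.linspace(-170.0, 170.0, 3401)
    engaged = []
    p2 = np.array([p_off, 0.0])
    for th in thetas:
        c, s = np.cos(np.deg2rad(th)), np.sin(np.deg2rad(th))
        s2 = np.array([c * s_off, s * s_off])
        seg = s2 - p2
        t = float(np.clip(-(p2 @ seg) / (seg @ seg), 0.0, 1.0))
        engaged.append(np.linalg.norm(p2 + t * seg) < radius)
    engaged = np.asarray(engaged)
    mtu.engagement_range_deg = (float(thetas[engaged].min()),
                                float(thetas[engaged].max())) if engaged.any() else None
    return model, mtu, wraps


# ---------------------------------------------------------------------------
# group-curve fixtures
# ---------------------------------------------------------------------------

def make_group_fixture(peak_angles, peak_magnitudes, grid=None,
                       width_deg: float = 60.0, joint: str = "hinge",
                       dof: str = "Z"):
    """Smooth synthetic moment-arm curves with planted peaks.

    Raised-cosine bumps: each curve peaks at exactly the requested angle
    (which must lie on the grid) with exactly the requested magnitude, and
    decays to zero ``width_deg`` away. Returns a list of
    :class:`MomentArmCurve` on the shared grid.
    """
    peak_angles = np.atleast_1d(np.asarray(peak_angles, dtype=float))
    peak_magnitudes = np.atleast_1d(np.asarray(peak_magnitudes, dtype=float))
    if len(peak_angles) != len(peak_magnitudes) or len(peak_angles) < 1:
        raise ValueError("need matching, non-empty peak angle/magnitude lists")
    grid = np.arange(-60.0, 61.0, 1.0) if grid is None else np.asarray(grid, dtype=float)
    curves = []
    for i, (pa, pm) in enumerate(zip(peak_angles, peak_magnitudes)):
        if pa < grid.min() or pa > grid.max():
            raise ValueError(f"peak angle {pa} outside grid")
        if not np.isclose(np.abs(grid - pa).min(), 0.0):
            raise ValueError(f"peak angle {pa} not on the grid")
        x = np.clip(np.abs(grid - pa) / width_deg, 0.0, 1.0)
        values = pm * 0.5 * (1.0 + np.cos(np.pi * x))
        curves.append(MomentArmCurve(f"synthetic_{i}", joint, dof, grid, values))
    return curves
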