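"""Geometry kernel: watertight-mesh mass properties, hulls, primitive fits.

All lengths are metres internally. Mesh readers accept a ``units`` flag so
that scan meshes digitized in millimetres can be converted on load.

Volume, centroid and inertia are computed for homogeneous solids bounded by
closed, outward-oriented triangle meshes via the divergence theorem
(signed tetrahedra against the origin); they are therefore invariant to
re-tessellation of the surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, MeshNotClosedError

logger = logging.getLogger(__name__)

__all__ = [
    "TriMesh",
    "AttachmentPatch",
    "load_mesh",
    "save_mesh",
    "mesh_volume",
    "mesh_centroid",
    "mesh_inertia",
    "convex_hull",
    "fit_sphere",
    "fit_cylinder",
    "uniform_scale",
    "mirror_x",
    "repair",
]


@dataclass
class TriMesh:
    """A triangle surface mesh: ``vertices`` (n, 3) metres, ``faces`` (m, 3) indices.

    Faces are assumed consistently oriented; outwardness is normalized by the
    volume operations (an inward-oriented closed mesh is flipped with a
    logged warning).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "mesh"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise ValueError("negative face index")

    # -- conversions -------------------------------------------------------
    @classmethod
    def from_trimesh(cls, tm: "trimesh.Trimesh", name: str = "mesh") -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float),
                   np.asarray(tm.faces, dtype=np.int64), name=name)

    def to_trimesh(self) -> "trimesh.Trimesh":
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    # -- topology ----------------------------------------------------------
    def boundary_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    @property
    def is_closed(self) -> bool:
        return self.faces.size > 0 and self.boundary_edge_count() == 0

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), name=self.name)

    def transformed(self, matrix: np.ndarray) -> "TriMesh":
        """Apply a 4x4 homogeneous transform to all vertices."""
        m = np.asarray(matrix, dtype=float)
        v = self.vertices @ m[:3, :3].T + m[:3, 3]
        faces = self.faces.copy()
        if np.linalg.det(m[:3, :3]) < 0:  # reflections invert orientation
            faces = faces[:, ::-1]
        return TriMesh(v, faces, name=self.name)


@dataclass
class AttachmentPatch:
    """A digitized origin or insertion surface: a subset of faces of a mesh.

    ``segment`` names the body segment the patch rides on (the frame its
    centroid is expressed in once assembled into a model).
    """

    mesh: TriMesh
    face_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    segment: str = ""

    def __post_init__(self):
        self.face_ids = np.asarray(self.face_ids, dtype=np.int64).ravel()
        if self.face_ids.size == 0:
            raise ValueError("attachment patch has no faces")
        if self.face_ids.max() >= len(self.mesh.faces) or self.face_ids.min() < 0:
            raise ValueError("patch face id not in referenced mesh")
        if self.area <= 0:
            raise ValueError("attachment patch has zero area")

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.vertices[self.mesh.faces[self.face_ids]]

    @property
    def area(self) -> float:
        t = self.triangles
        return float(0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_mesh(path, units: str = "m", name: str | None = None) -> TriMesh:
    """Load OBJ/STL/PLY. ``units='mm'`` converts coordinates to metres."""
    # process=True merges the per-facet duplicate vertices formats like STL
    # store, and drops degenerate faces; orientation is then normalized
    tm = trimesh.load_mesh(path, process=True)
    if isinstance(tm, trimesh.Scene):
        tm = tm.to_mesh()
    if tm.is_watertight:
        tm.fix_normals()
    mesh = TriMesh.from_trimesh(tm, name=name or str(path))
    if units == "mm":
        mesh.vertices *= 1e-3
    elif units != "m":
        raise ValueError(f"unknown unit flag {units!r} (use 'mm' or 'm')")
    return mesh


def save_mesh(mesh: TriMesh, path) -> None:
    mesh.to_trimesh().export(path)


# ---------------------------------------------------------------------------
# mass properties
# ---------------------------------------------------------------------------

def _require_closed(mesh: TriMesh) -> None:
    n = mesh.boundary_edge_count()
    if n or mesh.faces.size == 0:
        raise MeshNotClosedError(max(n, 1), name=mesh.name)


def _signed_volume(mesh: TriMesh) -> float:
    v = mesh.vertices
    f = mesh.faces
    return float(np.einsum(
        "ij,ij->", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])) / 6.0)


def _oriented(mesh: TriMesh) -> TriMesh:
    """Return the mesh with outward orientation (positive signed volume)."""
    if _signed_volume(mesh) < 0:
        logger.warning("%s: inward orientation detected; flipping faces", mesh.name)
        return TriMesh(mesh.vertices, mesh.faces[:, ::-1], name=mesh.name)
    return mesh


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume (m^3) of a closed mesh via the divergence theorem."""
    _require_closed(mesh)
    return abs(_signed_volume(mesh))


def mesh_centroid(mesh: TriMesh) -> np.ndarray:
    """Volume-weighted centroid of the enclosed solid (m)."""
    _require_closed(mesh)
    mesh = _oriented(mesh)
    v = mesh.vertices
    f = mesh.faces
    vols = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])) / 6.0
    # tetra centroid = (0 + v0 + v1 + v2) / 4
    cents = (v[f[:, 0]] + v[f[:, 1]] + v[f[:, 2]]) / 4.0
    total = vols.sum()
    if total <= 0:
        raise DegenerateGeometryError("mesh encloses no volume")
    return (cents * vols[:, None]).sum(axis=0) / total


def mesh_inertia(mesh: TriMesh, density: float):
    """Homogeneous-solid mass properties.

    Returns ``(mass kg, com (3,), inertia (3, 3) about the com)``; the
    inertia tensor is symmetric positive-definite for any solid with
    positive volume.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    _require_closed(mesh)
    tm = _oriented(mesh).to_trimesh()
    tm.density = density
    mass = float(tm.mass)
    com = np.asarray(tm.center_mass, dtype=float)
    inertia = np.asarray(tm.moment_inertia, dtype=float)  # about com, frame axes
    inertia = 0.5 * (inertia + inertia.T)  # enforce exact symmetry
    return mass, com, inertia


# ---------------------------------------------------------------------------
# convex hulls
# ---------------------------------------------------------------------------

def convex_hull(points: np.ndarray, name: str = "hull") -> TriMesh:
    """Convex hull of >= 4 non-coplanar points as a closed outward mesh."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points for a 3D hull")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-12 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are coplanar: no 3D hull")
    hull = trimesh.convex.convex_hull(pts)
    return _oriented(TriMesh.from_trimesh(hull, name=name))


# ---------------------------------------------------------------------------
# primitive fits (joint-centre estimation)
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray):
    """Least-squares sphere through >= 4 non-coplanar points.

    Algebraic (linear) fit followed by one Gauss-Newton geometric refinement;
    deterministic, no initial guess required.

    Returns ``(centre (3,), radius, rms_residual)``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points to fit a sphere")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError(
            "degenerate configuration: points are coplanar or collinear")
    # |x|^2 = 2 c.x + (r^2 - |c|^2)  -> linear in (c, k)
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    radius = float(np.sqrt(max(sol[3] + centre @ centre, 0.0)))

    def geom_residual(p):
        c, r = p[:3], p[3]
        return np.linalg.norm(pts - c, axis=1) - r

    res = least_squares(geom_residual, np.append(centre, radius),
                        method="lm", xtol=1e-12, ftol=1e-12)
    centre, radius = res.x[:3], float(abs(res.x[3]))
    rms = float(np.sqrt(np.mean(geom_residual(res.x) ** 2)))
    return centre, radius, rms


def fit_cylinder(points: np.ndarray):
    """Least-squares infinite cylinder through >= 6 points with axial extent.

    The axis is initialized from the principal direction of the point cloud
    and refined together with the radius by least squares on point-to-axis
    distance. Returns ``(axis_point (3,), axis_direction unit (3,), radius)``.

    Raises :class:`DegenerateGeometryError` when the cloud has no preferred
    axis (e.g. points on a sphere), reporting the anisotropy of its singular
    values.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 6:
        raise DegenerateGeometryError("need at least 6 points to fit a cylinder")
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    axis0 = vt[0]

    def to_axis(params):
        # params: axis point (2 comps in plane normal to axis0), direction (theta, phi), radius
        theta, phi = params[2], params[3]
        d = np.array([np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        # axis point parametrized in the plane orthogonal to the initial axis
        e1, e2 = _plane_basis(axis0)
        p0 = mean + params[0] * e1 + params[1] * e2
        rel = pts - p0
        dist = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
        return dist, d, p0

    def residual(params):
        dist, _, _ = to_axis(params)
        return dist - params[4]

    theta0 = float(np.arccos(np.clip(axis0[2], -1, 1)))
    phi0 = float(np.arctan2(axis0[1], axis0[0]))
    rel0 = centered - np.outer(centered @ axis0, axis0)
    r0 = float(np.linalg.norm(rel0, axis=1).mean())
    res = least_squares(residual, [0.0, 0.0, theta0, phi0, r0],
                        method="lm", xtol=1e-13, ftol=1e-13)
    dist, d, p0 = to_axis(res.x)
    radius = float(abs(res.x[4]))
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    if radius <= 0 or rms > 0.05 * radius:
        raise DegenerateGeometryError(
            "no preferred cylinder axis: residual rms "
            f"{rms:.3g} vs radius {radius:.3g}; singular values {sv.round(6)}")
    return p0, d / np.linalg.norm(d), radius


def _plane_basis(normal: np.ndarray):
    """Two unit vectors spanning the plane orthogonal to ``normal``."""
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# rigid-ish operations
# ---------------------------------------------------------------------------

def uniform_scale(mesh: TriMesh, factor: float, about=None) -> TriMesh:
    """Scale all vertices by ``factor`` about a point (default: the origin)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    about = np.zeros(3) if about is None else np.asarray(about, dtype=float)
    v = (mesh.vertices - about) * factor + about
    return TriMesh(v, mesh.faces.copy(), name=mesh.name)


def mirror_x(points: np.ndarray) -> np.ndarray:
    """Mirror points about the midsagittal plane x = 0 (pelvis-centred model).

    An involution: applying twice returns the input bitwise.
    """
    pts = np.array(points, dtype=float, copy=True)
    flat = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    pts[:, 0] = -pts[:, 0]
    return pts[0] if flat else pts


def repair(mesh: TriMesh, merge_tol: float = 1e-9) -> TriMesh:
    """Merge duplicate vertices and fill small holes; actions are logged.

    Offered separately from the mass-property operations, which reject open
    meshes rather than healing them silently.
    """
    tm = mesh.to_trimesh()
    before = len(tm.vertices)
    tm.merge_vertices(digits_vertex=int(-np.log10(merge_tol)))
    if before != len(tm.vertices):
        logger.info("%s: merged %d duplicate vertices", mesh.name, before - len(tm.vertices))
    if not tm.is_watertight:
        filled = tm.fill_holes()
        logger.info("%s: hole fill %s", mesh.name, "succeeded" if filled else "failed")
    tm.fix_normals()
    return TriMesh.from_trimesh(tm, name=mesh.name)
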