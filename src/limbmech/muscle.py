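"""Volumetric muscle bellies to lines of action and masses.

A muscle belly is a closed polygonal mesh with digitized origin and
insertion patches. Its line of action (LoA) is obtained by slicing the
belly with planes perpendicular to the origin-insertion chord and chaining
the area centroids of the cross-sections ("centroid threading"); the LoA is
then downsampled to model path points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import LimbmechError
from .mesh_core import AttachmentPatch, TriMesh, mesh_volume, _plane_basis

logger = logging.getLogger(__name__)

MUSCLE_TISSUE_DENSITY = 1060.0  # kg m^-3, standard skeletal-muscle value

__all__ = [
    "MUSCLE_TISSUE_DENSITY",
    "PolygonalMuscle",
    "LineOfAction",
    "patch_centroid",
    "thread_line_of_action",
    "muscle_mass",
    "normalize_mass",
    "loa_to_path",
    "belly_overlap_volume",
]


@dataclass
class PolygonalMuscle:
    """A volumetric muscle reconstruction.

    ``heads`` optionally lists extra insertion patches for multi-head units
    (e.g. long digital flexors/extensors: one belly, one mass, one LoA per
    head sharing the proximal course).
    """

    name: str
    belly: TriMesh
    origin: AttachmentPatch
    insertion: AttachmentPatch
    density: float = MUSCLE_TISSUE_DENSITY
    heads: list = field(default_factory=list)
    groups: list = field(default_factory=list)

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if not self.belly.is_closed:
            raise LimbmechError(f"{self.name}: belly mesh is not closed")
        if self.origin.segment and self.origin.segment == self.insertion.segment:
            raise LimbmechError(
                f"{self.name}: origin and insertion on the same segment "
                f"({self.origin.segment}); unit would cross no joint")


@dataclass
class LineOfAction:
    """Ordered 3D polyline; each point tagged with the segment frame it is
    fixed to. First point = origin-patch centroid, last = insertion-patch
    centroid."""

    points: np.ndarray              # (n, 3)
    segments: list                  # frame name per point

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise LimbmechError("line of action needs at least 2 points")
        if len(self.segments) != len(self.points):
            raise LimbmechError("one segment tag per point required")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps < 1e-12):
            raise LimbmechError("consecutive line-of-action points coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def mirrored(self) -> "LineOfAction":
        pts = self.points.copy()
        pts[:, 0] = -pts[:, 0]
        return LineOfAction(pts, list(self.segments))


def patch_centroid(patch: AttachmentPatch) -> np.ndarray:
    """Area-weighted centroid of an attachment patch."""
    tris = patch.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1)
    cents = tris.mean(axis=1)
    total = areas.sum()
    if total <= 0:
        raise LimbmechError("attachment patch has zero area")
    return (cents * areas[:, None]).sum(axis=0) / total


def _section_centroid(mesh: TriMesh, plane_origin, plane_normal):
    """Area centroid of the largest cross-section loop cut by a plane.

    Returns ``None`` when the plane misses the mesh. Multiple loops (e.g.
    near bifurcations) are resolved deterministically: the largest-area loop
    wins, logged at debug level.
    """
    tm = mesh.to_trimesh()
    section = tm.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if section is None:
        return None
    loops = [np.asarray(d) for d in section.discrete]
    if not loops:
        return None
    e1, e2 = _plane_basis(plane_normal)
    origin = np.asarray(plane_origin, dtype=float)
    best = None
    for loop in loops:
        rel = loop - origin
        xy = np.column_stack([rel @ e1, rel @ e2])
        if len(xy) < 3:
            continue
        poly = Polygon(xy)
        if not poly.is_valid or poly.area <= 0:
            continue
        if best is None or poly.area > best[0]:
            best = (poly.area, poly.centroid)
    if best is None:
        return None
    if len(loops) > 1:
        logger.debug("multi-loop slice: keeping largest of %d loops", len(loops))
    c = best[1]
    return origin + c.x * e1 + c.y * e2


def thread_line_of_action(muscle: PolygonalMuscle, n_slices: int = 20,
                          tip_margin: float = 0.025) -> LineOfAction:
    """Thread a line of action through the belly's cross-section centroids.

    The belly is sliced by ``n_slices`` planes perpendicular to the
    origin->insertion chord, evenly spaced between ``tip_margin`` and
    ``1 - tip_margin`` of the chord (avoiding degenerate tip intersections).
    Empty slices are skipped with a warning; if every slice is empty the
    belly does not span its chord and an error is raised.
    """
    o = patch_centroid(muscle.origin)
    i = patch_centroid(muscle.insertion)
    chord = i - o
    span = np.linalg.norm(chord)
    if span < 1e-12:
        raise LimbmechError(f"{muscle.name}: zero-length origin-insertion chord")
    normal = chord / span

    pts = [o]
    segs = [muscle.origin.segment or "origin"]
    n_empty = 0
    for t in np.linspace(tip_margin, 1.0 - tip_margin, n_slices):
        c = _section_centroid(muscle.belly, o + t * chord, normal)
        if c is None:
            n_empty += 1
            logger.warning("%s: empty slice at %.1f%% of chord", muscle.name, 100 * t)
            continue
        if np.linalg.norm(c - pts[-1]) < 1e-12:
            continue
        pts.append(c)
        segs.append("belly")
    if n_empty == n_slices:
        raise LimbmechError(
            f"{muscle.name}: all {n_slices} slices empty; belly does not span chord")
    if np.linalg.norm(i - pts[-1]) >= 1e-12:
        pts.append(i)
        segs.append(muscle.insertion.segment or "insertion")
    return LineOfAction(np.asarray(pts), segs)


def muscle_mass(muscle: PolygonalMuscle) -> float:
    """Belly mass in kg: mesh volume x tissue density."""
    return mesh_volume(muscle.belly) * muscle.density


def normalize_mass(muscle_mass_kg: float, segment_mass_kg: float) -> float:
    """Muscle mass as a fraction of its segment mass (dimensionless)."""
    if segment_mass_kg <= 0:
        raise ValueError("segment mass must be positive")
    return muscle_mass_kg / segment_mass_kg


def loa_to_path(loa: LineOfAction, max_points: int) -> LineOfAction:
    """Downsample a threaded line to at most ``max_points`` path points.

    Greatest-deviation-first (Douglas-Peucker style): endpoints are kept
    exactly; interior points are added in order of their distance from the
    current polyline until the budget is reached or the line is exact.
    """
    if max_points < 2:
        raise ValueError("max_points must be at least 2")
    pts = loa.points
    n = len(pts)
    if n <= max_points:
        return LineOfAction(pts.copy(), list(loa.segments))
    keep = {0, n - 1}
    while len(keep) < max_points:
        idx = sorted(keep)
        best = (0.0, None)
        for a, b in zip(idx[:-1], idx[1:]):
            if b - a < 2:
                continue
            seg = pts[a:b + 1]
            d = _polyline_deviation(seg)
            if d[0] > best[0]:
                best = (d[0], a + d[1])
        if best[1] is None:
            break
        keep.add(best[1])
    idx = sorted(keep)
    out = LineOfAction(pts[idx], [loa.segments[k] for k in idx])
    if loa.length > 0 and abs(out.length - loa.length) > 0.01 * loa.length:
        logger.warning("downsampled path length deviates %.2f%% from threaded line",
                       100 * abs(out.length - loa.length) / loa.length)
    return out


def _polyline_deviation(seg: np.ndarray):
    """Max distance of interior points from the chord of ``seg``; (dist, index)."""
    a, b = seg[0], seg[-1]
    ab = b - a
    denom = np.dot(ab, ab)
    rel = seg[1:-1] - a
    if denom < 1e-24:
        d = np.linalg.norm(rel, axis=1)
    else:
        t = np.clip(rel @ ab / denom, 0.0, 1.0)
        d = np.linalg.norm(rel - np.outer(t, ab), axis=1)
    k = int(np.argmax(d))
    return float(d[k]), k + 1


def belly_overlap_volume(a: PolygonalMuscle, b: PolygonalMuscle,
                         n_samples: int = 20000, seed: int = 0) -> float:
    """Monte Carlo estimate of the overlap volume between two bellies (m^3).

    Inter-muscle spacing is resolved at the volumetric modelling stage, not
    by this package; this check merely reports residual interpenetration so
    digitization problems surface. Estimates use a fixed seed and are
    reproducible.
    """
    rng = np.random.default_rng(seed)
    tm_a = a.belly.to_trimesh()
    tm_b = b.belly.to_trimesh()
    lo = np.maximum(tm_a.bounds[0], tm_b.bounds[0])
    hi = np.minimum(tm_a.bounds[1], tm_b.bounds[1])
    if np.any(hi <= lo):
        return 0.0
    box_vol = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = tm_a.contains(pts) & tm_b.contains(pts)
    return box_vol * float(inside.mean())
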