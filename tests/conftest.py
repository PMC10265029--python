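"""Shared fixtures: analytic meshes and minimal kinematic models."""

import numpy as np
import pytest
import trimesh

from limbmech.mesh_core import TriMesh
from limbmech.synthetic import (make_hinge_limb, make_spindle_muscle,
                                make_two_segment_limb, make_wrapped_muscle)


@pytest.fixture
def unit_cube():
    """Unit cube with min corner at the origin (12 triangles, outward)."""
    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    tm.apply_translation((0.5, 0.5, 0.5))
    return TriMesh.from_trimesh(tm, name="unit_cube")


@pytest.fixture
def icosphere():
    """Radius-1 icosphere, 4 subdivisions (volume within 0.5% of 4pi/3)."""
    return TriMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4),
                                name="icosphere")


@pytest.fixture
def hinge_model():
    return make_hinge_limb(rom=(-90.0, 90.0))


@pytest.fixture
def two_segment_limb():
    return make_two_segment_limb()


@pytest.fixture
def wrapped_fixture():
    """(model, mtu, wraps) with a coaxial joint cylinder: arm == radius."""
    return make_wrapped_muscle(radius=0.03)


@pytest.fixture
def spindle():
    return make_spindle_muscle(r0=0.02, length=0.3, resolution=64)


def make_bent_tube(bend_radius=0.2, tube_radius=0.02, n_u=64, n_v=48):
    """Quarter-torus tube (medial axis: circle of radius ``bend_radius`` in
    the xy-plane from angle 0 to 90 degrees), closed with end caps."""
    us = np.linspace(0.0, np.pi / 2.0, n_u)
    vs = np.linspace(0.0, 2.0 * np.pi, n_v, endpoint=False)
    verts = []
    for u in us:
        centre = bend_radius * np.array([np.cos(u), np.sin(u), 0.0])
        radial = np.array([np.cos(u), np.sin(u), 0.0])
        for v in vs:
            verts.append(centre + tube_radius * (np.cos(v) * radial
                                                 + np.sin(v) * np.array([0, 0, 1.0])))
    start_c = len(verts)
    verts.append(bend_radius * np.array([1.0, 0.0, 0.0]))
    end_c = len(verts)
    verts.append(bend_radius * np.array([0.0, 1.0, 0.0]))

    def vid(i, k):
        return i * n_v + (k % n_v)

    faces = []
    for i in range(n_u - 1):
        for k in range(n_v):
            a, b = vid(i, k), vid(i, k + 1)
            c, d = vid(i + 1, k + 1), vid(i + 1, k)
            faces.append([a, c, b])
            faces.append([a, d, c])
    for k in range(n_v):  # caps
        faces.append([start_c, vid(0, k), vid(0, k + 1)])
        faces.append([end_c, vid(n_u - 1, k + 1), vid(n_u - 1, k)])
    mesh = TriMesh(np.asarray(verts), np.asarray(faces), name="bent_tube")
    cap_faces_start = np.flatnonzero(
        (np.asarray(faces) == start_c).any(axis=1))
    cap_faces_end = np.flatnonzero((np.asarray(faces) == end_c).any(axis=1))
    return mesh, cap_faces_start, cap_faces_end
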