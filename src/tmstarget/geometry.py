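"""Spherical and mesh geometry primitives.

All lengths are millimetres; the head coordinate frame is RAS
(x right, y anterior, z superior) with the origin at the sphere centre.
Scalp geodesics default to exact great-circle arcs because the synthetic
scalp is an analytic sphere; a discrete Dijkstra shortest path over the
triangulation is available for non-spherical surfaces.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

__all__ = [
    "unit",
    "rotate_about_axis",
    "arc_angle",
    "sphere_geodesic",
    "slerp",
    "geodesic_midpoint",
    "tangent_basis",
    "toward_midline",
    "make_sphere_mesh",
    "mesh_geodesic",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize the last axis of ``v`` to unit length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize a zero vector")
    return v / n


def rotate_about_axis(points: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate ``points`` about ``axis`` through the origin by ``angle_rad``."""
    rot = Rotation.from_rotvec(unit(axis) * angle_rad)
    return rot.apply(np.atleast_2d(points)).reshape(np.shape(points))


def arc_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle (rad) between two direction vectors, numerically stable."""
    uu, vv = unit(u), unit(v)
    return float(2.0 * np.arcsin(np.clip(np.linalg.norm(uu - vv) / 2.0, 0.0, 1.0)))


def sphere_geodesic(p: np.ndarray, q: np.ndarray, radius: float) -> float:
    """Great-circle distance (mm) between two points on a sphere about the origin."""
    return radius * arc_angle(p, q)


def slerp(p: np.ndarray, q: np.ndarray, frac: float) -> np.ndarray:
    """Point at ``frac`` of the great-circle arc from ``p`` to ``q`` (same radius)."""
    r = np.linalg.norm(p)
    u, v = unit(p), unit(q)
    ang = arc_angle(u, v)
    if ang < 1e-12:
        return np.asarray(p, dtype=float)
    if abs(ang - np.pi) < 1e-9:
        raise ValueError("antipodal points: great-circle arc is not unique")
    w = (np.sin((1 - frac) * ang) * u + np.sin(frac * ang) * v) / np.sin(ang)
    return r * unit(w)


def geodesic_midpoint(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return slerp(p, q, 0.5)


def tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (t1, t2) of the plane orthogonal to ``normal``."""
    n = unit(normal)
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = unit(np.cross(ref, n))
    t2 = np.cross(n, t1)
    return t1, t2


def toward_midline(position: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Unit tangent-plane direction pointing toward the sagittal (x=0) plane.

    For points on the midline itself the direction is degenerate; the
    anterior (+y) tangent direction is returned instead.
    """
    n = unit(normal)
    d = np.array([-np.sign(position[0]), 0.0, 0.0])
    if position[0] == 0.0:
        d = np.array([0.0, 1.0, 0.0])
    t = d - (d @ n) * n
    nt = np.linalg.norm(t)
    if nt < 1e-9:
        d = np.array([0.0, 1.0, 0.0])
        t = d - (d @ n) * n
        nt = np.linalg.norm(t)
    return t / nt


def make_sphere_mesh(radius: float, target_edge_mm: float = 6.0) -> trimesh.Trimesh:
    """Icosphere with vertices at exactly ``radius`` and edges near the target length.

    The subdivision level is the smallest one whose mean edge length does not
    exceed ``target_edge_mm`` (capped at 5 to bound memory).
    """
    if radius <= 0 or target_edge_mm <= 0:
        raise ValueError("radius and target edge length must be positive")
    # level-0 icosahedron edge ~ 1.0515 * radius, halved per subdivision
    level = int(np.clip(np.ceil(np.log2(1.0515 * radius / target_edge_mm)), 0, 5))
    return trimesh.creation.icosphere(subdivisions=level, radius=radius)


def mesh_geodesic(mesh: trimesh.Trimesh, p: np.ndarray, q: np.ndarray) -> float:
    """Discrete shortest-path length along mesh edges between the vertices
    nearest ``p`` and ``q``.  Upper bound on the true surface geodesic; used
    only when the scalp is not an analytic sphere."""
    import networkx as nx

    g = nx.Graph()
    edges = mesh.edges_unique
    lengths = mesh.edges_unique_length
    g.add_weighted_edges_from(
        (int(a), int(b), float(w)) for (a, b), w in zip(edges, lengths)
    )
    i = int(np.argmin(np.linalg.norm(mesh.vertices - np.asarray(p), axis=1)))
    j = int(np.argmin(np.linalg.norm(mesh.vertices - np.asarray(q), axis=1)))
    return float(nx.shortest_path_length(g, i, j, weight="weight"))
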