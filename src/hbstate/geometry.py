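"""Small geometric primitives shared across modules.

All coordinates are in Angstrom in a right-handed frame; angles returned in
degrees. These helpers are deliberately free of any structure-model
dependency so they can be unit-tested on bare arrays.
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a rotation of ``angle_deg`` about ``axis``.

    Rodrigues' formula; ``axis`` need not be normalised.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise DegenerateGeometryError("rotation axis has zero length")
    k = axis / n
    t = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation,
                origin=None) -> np.ndarray:
    """Apply ``x -> R (x - o) + o + t`` to an (n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    t = np.asarray(translation, dtype=float)
    if origin is None:
        return coords @ rotation.T + t
    o = np.asarray(origin, dtype=float)
    return (coords - o) @ rotation.T + o + t


def is_proper_rotation(matrix: np.ndarray, tol: float = 1e-6) -> bool:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        return False
    return (np.allclose(m @ m.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(m) - 1.0) <= tol)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    atan2 formulation: robust for near-planar configurations.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 onto +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def fit_plane(points: np.ndarray):
    """Orthogonal least-squares plane through ``points``.

    Returns ``(centroid, unit_normal)``. Raises for degenerate (collinear)
    configurations where the plane is not unique.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s.size < 3 or s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    return centroid, vt[2]


def fit_line(points: np.ndarray):
    """Orthogonal least-squares line through ``points``.

    Returns ``(centroid, unit_direction)``.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[0] < 1e-8:
        raise DegenerateGeometryError("points are coincident; line undefined")
    return centroid, vt[0]


def point_line_distance(point, centroid, direction) -> float:
    d = np.asarray(point, dtype=float) - np.asarray(centroid, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    return float(np.linalg.norm(d - (d @ u) * u))


def angle_between(v1, v2) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    c = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d.

    Returns the position of d such that |c-d| = ``bond``, angle(b, c, d) =
    ``angle_deg`` and dihedral(a, b, c, d) = ``dihedral_deg``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateGeometryError("reference atoms collinear in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.cos(dih) * np.sin(ang),
                        -bond * np.sin(dih) * np.sin(ang)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
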