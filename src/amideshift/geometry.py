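"""Small vector-geometry toolkit: angles, dihedrals, NeRF atom placement.

All positions are Cartesian, in Angstrom; angles are returned in degrees
with the IUPAC sign convention for dihedrals (right-handed, in (-180, 180]).
"""

from __future__ import annotations

import numpy as np

_DEG = 180.0 / np.pi


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u, w = unit(a - b), unit(c - b)
    return float(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0)) * _DEG)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion p0-p1-p2-p3 in degrees, IUPAC sign, range (-180, 180].

    Raises ValueError when the four points are degenerate (collinear
    segments), where the torsion is undefined.
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: collinear atoms")
    m1 = np.cross(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.arctan2(y, x) * _DEG)
    return 180.0 if ang == -180.0 else ang


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom D bonded to C.

    Given positions of A, B, C, returns D such that |C-D| = length,
    angle(B, C, D) = ``angle`` and dihedral(A, B, C, D) = ``torsion``
    (both in degrees).
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = length * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    k = unit(axis)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Best-fit plane normal of an (n, 3) point set via SVD; unit length.

    The sign is fixed so the first nonzero component is positive, which makes
    the result independent of point ordering up to a global flip.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[-1]
    for comp in n:
        if abs(comp) > 1e-12:
            if comp < 0:
                n = -n
            break
    return n
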