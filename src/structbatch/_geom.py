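"""Small 3D geometry helpers shared by the builders and analyses.

All coordinates are in Angstroms, all angles in degrees unless a name says
otherwise. The workhorse is :func:`place_atom` (the NeRF construction): given
three already-placed atoms and internal coordinates (bond length, bond angle,
dihedral) it returns the position of the next atom. Backbones, side chains and
fixtures are all grown with it, so geometry is exactly reproducible.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "angle_deg",
    "rotation_about_axis",
    "unit",
]


def _cross3(u, v):
    # np.cross has high call overhead for single 3-vectors
    return np.array([u[1] * v[2] - u[2] * v[1],
                     u[2] * v[0] - u[0] * v[2],
                     u[0] * v[1] - u[1] * v[0]])


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalised; raises on zero vectors."""
    v = np.asarray(v, float)
    n = math.sqrt(float(v[0] * v[0] + v[1] * v[1] + v[2] * v[2]))
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, theta: float, chi: float) -> np.ndarray:
    """Position atom D so that |C-D| = bond, angle(B,C,D) = theta and
    dihedral(A,B,C,D) = chi (degrees).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    th = math.radians(theta)
    ph = math.radians(chi)
    bc = unit(c - b)
    n = unit(_cross3(b - a, bc))
    m = _cross3(n, bc)
    sin_th = math.sin(th)
    return (c - bond * math.cos(th) * bc
            + bond * sin_th * math.cos(ph) * m
            - bond * sin_th * math.sin(ph) * n)


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    m1 = _cross3(n1, unit(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    v1 = unit(np.asarray(p1, float) - np.asarray(p2, float))
    v2 = unit(np.asarray(p3, float) - np.asarray(p2, float))
    return float(np.rad2deg(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about `axis` (Rodrigues)."""
    k = unit(np.asarray(axis, float))
    th = np.deg2rad(angle_deg_)
    kx = np.array([[0, -k[2], k[1]],
                   [k[2], 0, -k[0]],
                   [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * kx + (1.0 - np.cos(th)) * (kx @ kx)
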