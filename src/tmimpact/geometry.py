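"""Low-level vector geometry: internal-coordinate atom placement (NeRF),
dihedrals, bond angles and rotation matrices."""

from __future__ import annotations

import numpy as np

Vec = np.ndarray


def unit(v: Vec) -> Vec:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: Vec, b: Vec, c: Vec) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0: Vec, p1: Vec, p2: Vec, p3: Vec) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(a: Vec, b: Vec, c: Vec, bond: float, angle: float,
               torsion: float) -> Vec:
    """Place atom d so that |d-c| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (NeRF construction; angles in degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_x(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rotation_y(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rotation_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotation_about_axis(axis: Vec, deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    a = unit(np.asarray(axis, dtype=float))
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(a, a)


def rotation_aligning(src: Vec, dst: Vec) -> np.ndarray:
    """Smallest rotation carrying unit direction src onto dst."""
    u, w = unit(np.asarray(src, float)), unit(np.asarray(dst, float))
    d = float(np.dot(u, w))
    if d > 1.0 - 1e-12:
        return np.eye(3)
    if d < -1.0 + 1e-12:
        # pick any perpendicular axis for the half-turn
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(u, helper))
        return rotation_about_axis(axis, 180.0)
    axis = unit(np.cross(u, w))
    return rotation_about_axis(axis, float(np.degrees(np.arccos(np.clip(d, -1, 1)))))


def helix_axis(ca_coords: np.ndarray) -> Vec:
    """Axis direction of a regular helix from its CA trace.

    Second differences of consecutive points on an ideal helix are purely
    radial, i.e. perpendicular to the axis; the axis is therefore the
    smallest principal direction of the stacked second differences.
    Requires at least 4 points.  The sign is chosen to point from the first
    CA towards the last.
    """
    p = np.asarray(ca_coords, dtype=float)
    if len(p) < 4:
        raise ValueError("need >= 4 CA positions to define a helix axis")
    d2 = p[2:] - 2 * p[1:-1] + p[:-2]
    _, _, vt = np.linalg.svd(d2 - d2.mean(axis=0) * 0.0)
    axis = vt[-1]
    if np.dot(axis, p[-1] - p[0]) < 0:
        axis = -axis
    return unit(axis)
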