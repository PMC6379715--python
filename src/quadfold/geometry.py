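"""Small vector-geometry utilities shared across the package.

All coordinates are in Angstrom, all angles in degrees unless noted.
"""
from __future__ import annotations

import numpy as np


def torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, in [0, 360)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(-y, x))) % 360.0


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Bond angle at p1, degrees in [0, 180]."""
    v0 = p0 - p1
    v2 = p2 - p1
    c = np.dot(v0, v2) / (np.linalg.norm(v0) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def wrap_angle_diff(a: float | np.ndarray, b: float | np.ndarray):
    """Signed circular difference a-b mapped to (-180, 180]."""
    d = (np.asarray(a) - np.asarray(b)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def rotation_z(angle_deg: float) -> np.ndarray:
    return rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg)


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal superposition of ``mobile`` onto ``target`` (both (n,3)).

    Returns (R, t, rmsd) with x' = x @ R.T + t, using the SVD solution with
    proper-rotation (det=+1) correction.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    A = mobile - mc
    B = target - tc
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = A @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    t = tc - mc @ R.T
    return R, t, rmsd


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of two (n,3) coordinate sets after optimal rigid superposition."""
    return kabsch(a, b)[2]


def best_fit_plane(points: np.ndarray):
    """Least-squares plane of (n,3) points.

    Returns (centroid, unit normal, rms deviation).
    """
    c = points.mean(axis=0)
    X = points - c
    # normal = eigenvector of the scatter matrix with the smallest eigenvalue
    w, V = np.linalg.eigh(X.T @ X)
    n = V[:, 0]
    dev = X @ n
    return c, n, float(np.sqrt(np.mean(dev**2)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
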