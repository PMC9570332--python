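"""Low-level vector geometry: angles, dihedrals, internal-coordinate placement,
and the Kabsch least-squares rigid superposition."""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle_deg",
    "dihedral_deg",
    "place_atom",
    "kabsch",
    "rotation_angle_deg",
    "rotation_axis",
    "rotation_about_axis",
]


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention, (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d such that |d-c| = bond, angle(b,c,d) = `angle` (deg) and
    dihedral(a,b,c,d) = `dihedral` (deg).  The NeRF internal-to-Cartesian step.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("place_atom: reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(moving: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of `moving` onto `target`.

    Returns ``(R, t, rmsd)`` with the proper rotation (det = +1) and translation
    minimising the (weighted) RMSD of ``R @ x + t`` against the target points.

    Parameters
    ----------
    moving, target : (n, 3) arrays, n >= 3, not all collinear.
    weights : optional (n,) non-negative weights (e.g. atomic masses).
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("kabsch: point sets must both be (n, 3)")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("kabsch: need at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("kabsch: weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ moving
    mu_t = w @ target
    x = moving - mu_m
    y = target - mu_t
    # covariance of the two centred clouds
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:
        raise ValueError("kabsch: degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = mu_t - rot @ mu_m
    diff = (moving @ rot.T + t) - target
    rmsd = float(np.sqrt(np.sum(w * np.sum(diff * diff, axis=1))))
    return rot, t, rmsd


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Angle of a proper rotation matrix: arccos((trace(R) - 1) / 2), degrees."""
    tr = float(np.trace(np.asarray(rotation, float)))
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def rotation_axis(rotation: np.ndarray) -> np.ndarray:
    """Unit rotation axis of a proper rotation (undefined sign fixed so the
    largest-magnitude component is positive).  Returns zeros for the identity."""
    rotation = np.asarray(rotation, float)
    # eigenvector for eigenvalue +1
    w, v = np.linalg.eig(rotation)
    idx = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, idx])
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9 or rotation_angle_deg(rotation) < 1e-6:
        return np.zeros(3)
    axis = axis / nrm
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix for a rotation of `angle_deg_` degrees about `axis`."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg_)
    c, s = np.cos(th), np.sin(th)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)
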