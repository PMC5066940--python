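"""Low-level vector geometry: torsion angles, frames, internal-coordinate placement.

Conventions
-----------
Torsions follow the IUPAC sign convention: looking down the p2->p3 bond,
a clockwise rotation of the far bond relative to the near bond is positive.
``signed`` angles live in (-180, 180], ``unsigned`` in [0, 360).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_signed",
    "wrap_unsigned",
    "angular_distance",
    "bond_angle",
    "dihedral",
    "place_atom",
    "kabsch",
    "orthonormalize",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (coincident or collinear points)."""


def wrap_signed(x):
    """Wrap angle(s) in degrees into (-180, 180]."""
    w = np.asarray(x, dtype=float) % 360.0
    w = np.where(w > 180.0, w - 360.0, w)
    return float(w) if np.isscalar(x) or np.ndim(x) == 0 else w


def wrap_unsigned(x):
    """Wrap angle(s) in degrees into [0, 360)."""
    w = np.asarray(x, dtype=float) % 360.0
    w = np.where(w >= 360.0, 0.0, w)  # tiny negatives round up to 360.0
    return float(w) if np.isscalar(x) or np.ndim(x) == 0 else w


def angular_distance(a: float, b: float) -> float:
    """Shortest arc (degrees, in [0, 180]) between two angles."""
    return abs(wrap_signed(a - b))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise GeometryError("coincident points in bond angle")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1, p2, p3, p4, range: str = "signed") -> float:
    """Torsion angle defined by four points, in degrees.

    Parameters
    ----------
    p1, p2, p3, p4
        Cartesian 3-vectors (Å).
    range
        ``"signed"`` maps to (-180, 180], ``"unsigned"`` to [0, 360).

    Raises
    ------
    GeometryError
        If consecutive points coincide or three consecutive points are
        collinear (the torsion is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("three collinear points in dihedral")
    # atan2 form is numerically stable near 0 and 180 degrees; the sign is
    # the IUPAC convention (clockwise positive looking from p2 toward p3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = -np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if range == "signed":
        return wrap_signed(ang)
    if range == "unsigned":
        return wrap_unsigned(ang)
    raise ValueError(f"unknown range convention {range!r}")


def place_atom(p1, p2, p3, length: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth atom by internal coordinates (NeRF construction).

    The new atom D is positioned so that ``|C-D| = length``, the bond angle
    B-C-D equals ``angle`` (degrees) and the torsion A-B-C-D equals
    ``torsion`` (degrees), for A=p1, B=p2, C=p3.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    d_local = length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise GeometryError("collinear reference atoms in place_atom")
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def kabsch(moving: np.ndarray, target: np.ndarray, allow_reflection: bool = False):
    """Optimal least-squares rotation R and translation t mapping moving onto target.

    Returns ``(R, t, rmsd)`` with ``target ≈ moving @ R.T + t`` and R proper
    (det +1) unless ``allow_reflection``.
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape or moving.shape[0] < 3:
        raise ValueError("need matching coordinate sets of >= 3 atoms")
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    H = (moving - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if not allow_reflection and d < 0:
        D = np.diag([1.0, 1.0, -1.0])
        R = Vt.T @ D @ U.T
    else:
        R = Vt.T @ U.T
    t = ct - R @ cm
    diff = (moving @ R.T + t) - target
    rmsd = float(np.sqrt((diff ** 2).sum() / moving.shape[0]))
    return R, t, rmsd


def orthonormalize(M: np.ndarray) -> np.ndarray:
    """Nearest proper rotation to a 3x3 matrix (polar decomposition via SVD)."""
    U, _, Vt = np.linalg.svd(np.asarray(M, float))
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R
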