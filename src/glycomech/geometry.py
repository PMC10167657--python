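"""Elementary vector geometry: distances and signed dihedral angles.

All coordinates are Cartesian in Angstrom.  Dihedrals follow the IUPAC
sign convention: looking from the second atom toward the third, a
clockwise rotation of the far bond relative to the near bond is positive.
"""

from __future__ import annotations

import numpy as np

__all__ = ["distance", "dihedral", "angle", "GeometryError"]

_DEGENERATE_TOL = 1e-8


class GeometryError(ValueError):
    """Raised for degenerate geometric input (coincident or collinear points)."""


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeometryError("non-finite coordinates")
    return v


def distance(a, b) -> float:
    """Euclidean distance between two points in Angstrom."""
    return float(np.linalg.norm(_as_vec(a) - _as_vec(b)))


def angle(a, b, c) -> float:
    """Bond angle a-b-c in degrees."""
    u = _as_vec(a) - _as_vec(b)
    v = _as_vec(c) - _as_vec(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERATE_TOL or nv < _DEGENERATE_TOL:
        raise GeometryError("coincident points in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    A cis (eclipsed) arrangement returns 0, anti-periplanar returns 180.
    Raises :class:`GeometryError` if consecutive points coincide or three
    consecutive points are collinear (the torsion is then undefined).
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < _DEGENERATE_TOL:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERATE_TOL or np.linalg.norm(n2) < _DEGENERATE_TOL:
        raise GeometryError("collinear points in dihedral")
    b2u = b2 / np.linalg.norm(b2)
    m = np.cross(b2u, n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang
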