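"""Cremer-Pople puckering analysis of six-membered rings.

The puckering of a 6-ring is described by the amplitude-phase triplet
(Q, theta, phi): out-of-plane displacements z_j of the ring atoms from the
Cremer-Pople mean plane are decomposed into an m=2 wave of amplitude q2 and
phase phi and an alternating m=3 component q3, with

    q2 cos(phi) =  sqrt(1/3) * sum_j z_j cos(4 pi j / 6)
    q2 sin(phi) = -sqrt(1/3) * sum_j z_j sin(4 pi j / 6)
    q3          =  sqrt(1/6) * sum_j (-1)^j z_j
    Q^2 = q2^2 + q3^2,   cos(theta) = q3 / Q.

Atom index j runs from 0 at the ring oxygen through C1...C5 (O5, C1, C2,
C3, C4, C5 for a pyranose).  With this origin and direction a
beta-D-glucopyranose 4C1 chair sits at the north pole (theta ~ 0), which is
the convention used throughout for conformer names: chairs at the poles,
boats and twist-boats (skew-boats) on the equator every 30 degrees of phi,
envelopes and half-chairs on the tropics near theta = 54.7 / 50.8 degrees
and their southern mirrors.

Cartesian puckering coordinates are qx = Q sin(theta) cos(phi),
qy = Q sin(theta) sin(phi), qz = Q cos(theta).  The collective variables
used for conformational free-energy landscapes are u = qx/Q, v = qy/Q,
which live on the unit disk (u^2 + v^2 = sin^2 theta <= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import GeometryError

__all__ = [
    "RingAtoms",
    "PuckerCoords",
    "ConformerLabel",
    "PuckerCV",
    "StoddartRegion",
    "cremer_pople",
    "assign_conformer",
    "stoddart_region",
    "pucker_cv",
    "inverse_cp",
    "reference_conformers",
    "PLANAR_Q_THRESHOLD",
]

PLANAR_Q_THRESHOLD = 0.1  # Angstrom; below this the ring is called planar

PYRANOSE_LABELS = ("O5", "C1", "C2", "C3", "C4", "C5")

# locant symbols in ring order: the ring oxygen is written 'O'
_LOCANTS = ("O", "1", "2", "3", "4", "5")


@dataclass(frozen=True)
class RingAtoms:
    """Six ordered ring-atom positions, starting at the ring oxygen."""

    positions: np.ndarray            # (6, 3) Angstrom
    labels: tuple[str, ...] = PYRANOSE_LABELS

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (6, 3):
            raise GeometryError(f"RingAtoms needs 6 positions, got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise GeometryError("non-finite ring coordinates")
        object.__setattr__(self, "positions", pos)
        if len(self.labels) != 6:
            raise GeometryError("RingAtoms needs 6 labels")

    def bond_lengths(self) -> np.ndarray:
        p = self.positions
        return np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)


@dataclass(frozen=True)
class PuckerCoords:
    Q: float          # total amplitude, Angstrom
    q2: float
    q3: float
    theta: float      # degrees, [0, 180]
    phi: float        # degrees, [0, 360); 0 with at_pole=True when undefined
    at_pole: bool = False

    @property
    def qx(self) -> float:
        return self.Q * math.sin(math.radians(self.theta)) * math.cos(math.radians(self.phi))

    @property
    def qy(self) -> float:
        return self.Q * math.sin(math.radians(self.theta)) * math.sin(math.radians(self.phi))

    @property
    def qz(self) -> float:
        return self.Q * math.cos(math.radians(self.theta))


@dataclass(frozen=True)
class ConformerLabel:
    label: str            # e.g. "4C1", "1S3", "4H3", "E3", "B1,4", "planar"
    arc_distance: float   # great-circle distance (degrees) to the reference point


@dataclass(frozen=True)
class PuckerCV:
    u: float   # qx / Q
    v: float   # qy / Q


@dataclass(frozen=True)
class StoddartRegion:
    hemisphere: str        # "north" | "south" | "pole"
    quadrant: int          # 0..3 for phi in [0,90), [90,180), [180,270), [270,360); -1 at poles
    tag: str               # human-readable tag listing member conformers
    members: tuple[str, ...]


def cremer_pople(ring: RingAtoms) -> PuckerCoords:
    """Puckering coordinates of a six-membered ring.

    The mean plane passes through the geometric center with normal along
    the cross product of the sine- and cosine-weighted position sums; the
    out-of-plane displacements then satisfy sum(z_j) = 0 exactly.

    Cyclically relabeling the ring start by k atoms never changes Q,
    shifts phi by 120*k degrees (mod 360), and mirrors theta -> 180-theta
    when k is odd (the alternating q3 component changes sign).
    """
    pos = ring.positions - ring.positions.mean(axis=0)
    j = np.arange(6)
    sin_w = np.sin(2 * np.pi * j / 6)
    cos_w = np.cos(2 * np.pi * j / 6)
    r_sin = (pos * sin_w[:, None]).sum(axis=0)
    r_cos = (pos * cos_w[:, None]).sum(axis=0)
    n = np.cross(r_sin, r_cos)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate ring: cannot define a mean plane")
    n /= norm
    z = pos @ n

    q2cos = math.sqrt(1.0 / 3.0) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    q2sin = -math.sqrt(1.0 / 3.0) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q3 = math.sqrt(1.0 / 6.0) * float((z * (-1.0) ** j).sum())
    q2 = math.hypot(q2cos, q2sin)
    Q = math.hypot(q2, q3)

    if Q < 1e-12:
        return PuckerCoords(Q=0.0, q2=0.0, q3=0.0, theta=0.0, phi=0.0, at_pole=True)
    theta = math.degrees(math.atan2(q2, q3))
    if q2 < 1e-10 * max(Q, 1.0):
        # at a pole phi is undefined; report 0 with a flag
        return PuckerCoords(Q=Q, q2=q2, q3=q3, theta=theta, phi=0.0, at_pole=True)
    phi = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    if phi >= 360.0:          # guard the 360.0 float wrap
        phi = 0.0
    return PuckerCoords(Q=Q, q2=q2, q3=q3, theta=theta, phi=phi)


# ---------------------------------------------------------------------------
# canonical conformer reference table
# ---------------------------------------------------------------------------

def _sup_sub_name(kind: str, above: tuple[int, ...], below: tuple[int, ...]) -> str:
    """IUPAC-style name: superscript locants (atoms above) prefix the letter,
    subscript locants (below) follow, e.g. above=(4,) below=(3,) kind=H -> 4H3."""
    key = lambda i: (i == 0, i)   # numeric locants ascending, then O last
    sup = ",".join(_LOCANTS[i] for i in sorted(above, key=key))
    sub = ",".join(_LOCANTS[i] for i in sorted(below, key=key))
    return f"{sup}{kind}{sub}"


def _theta_phi_from_z(z: np.ndarray) -> tuple[float, float]:
    j = np.arange(6)
    q2cos = math.sqrt(1.0 / 3.0) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    q2sin = -math.sqrt(1.0 / 3.0) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q3 = math.sqrt(1.0 / 6.0) * float((z * (-1.0) ** j).sum())
    q2 = math.hypot(q2cos, q2sin)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(q2sin, q2cos)) % 360.0 if q2 > 1e-12 else 0.0
    return theta, phi


@lru_cache(maxsize=1)
def reference_conformers() -> dict[str, tuple[float, float]]:
    """(theta, phi) of the 38 canonical 6-ring conformers.

    Generated from the ideal displacement patterns rather than a hard-coded
    table: chairs are alternating z patterns, a boat raises (or lowers) two
    para atoms, a twist-boat displaces two para atoms oppositely, an
    envelope displaces a single atom, a half-chair displaces two adjacent
    atoms oppositely.  The (theta, phi) of each pattern follows from the
    Cremer-Pople projection, placing boats/twist-boats on the equator every
    30 degrees, envelopes at theta = 54.74/125.26 and half-chairs at
    theta = 50.77/129.23 degrees.
    """
    table: dict[str, tuple[float, float]] = {}

    def put(name: str, z: np.ndarray):
        table[name] = _theta_phi_from_z(z)

    e = np.eye(6)
    alt = np.array([(-1.0) ** k for k in range(6)])

    # chairs: 4C1 has C4 (j=4) up, C1 (j=1) down -> +alt pattern
    put("4C1", alt)
    put("1C4", -alt)

    # boats: para atoms (j, j+3) both displaced to the same side
    for a in range(3):
        b = a + 3
        put(_sup_sub_name("B", (a, b), ()), e[a] + e[b])
        put(_sup_sub_name("B", (), (a, b)), -(e[a] + e[b]))

    # twist-boats (skew-boats): canonical six, named by one atom up / one down
    for a, b in [(1, 3), (3, 1), (1, 5), (5, 1), (0, 2), (2, 0)]:
        put(_sup_sub_name("S", (a,), (b,)), e[a] - e[b])

    # envelopes: a single atom out of the plane of the other five
    for a in range(6):
        put(_sup_sub_name("E", (a,), ()), e[a])
        put(_sup_sub_name("E", (), (a,)), -e[a])

    # half-chairs: adjacent atoms displaced to opposite sides
    for a in range(6):
        b = (a + 1) % 6
        put(_sup_sub_name("H", (a,), (b,)), e[a] - e[b])
        put(_sup_sub_name("H", (b,), (a,)), e[b] - e[a])

    assert len(table) == 38
    return table


def _arc_distance(theta1: float, phi1: float, theta2: float, phi2: float) -> float:
    """Great-circle distance in degrees between two (theta, phi) sphere points."""
    t1, p1, t2, p2 = map(math.radians, (theta1, phi1, theta2, phi2))
    cosd = (math.cos(t1) * math.cos(t2)
            + math.sin(t1) * math.sin(t2) * math.cos(p1 - p2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosd))))


def assign_conformer(pc: PuckerCoords,
                     q_planar_threshold: float = PLANAR_Q_THRESHOLD) -> ConformerLabel:
    """Nearest canonical conformer by great-circle distance on the sphere.

    Rings with Q below the planar threshold are labelled "planar".  Ties in
    arc distance are broken by lexicographic label order (deterministic).
    """
    if pc.Q < q_planar_threshold:
        return ConformerLabel(label="planar", arc_distance=0.0)
    best_label = None
    best_d = math.inf
    for label in sorted(reference_conformers()):
        t, p = reference_conformers()[label]
        d = _arc_distance(pc.theta, pc.phi, t, p)
        if d < best_d - 1e-12:
            best_d = d
            best_label = label
    return ConformerLabel(label=best_label, arc_distance=best_d)


# Stoddart quadrants: phi bins of 90 degrees; the polar caps are their own
# central regions (4C1 north, 1C4 south).  Boundary points fall in the
# lower-phi quadrant (documented tie-break).
_POLAR_CAP_THETA = 25.0  # degrees from the pole counted as the chair region


def stoddart_region(pc: PuckerCoords) -> StoddartRegion:
    """Quadrant of the northern/southern Stoddart projection containing a point.

    The Stoddart diagram is the polar projection of the puckering sphere;
    here each hemisphere is split into a central chair cap (theta within
    25 degrees of the pole) and four 90-degree phi quadrants starting at
    phi = 0.  The tag lists the canonical conformers whose reference points
    fall inside the region.
    """
    if pc.Q < PLANAR_Q_THRESHOLD:
        raise GeometryError("planar ring has no Stoddart position")
    if pc.theta <= _POLAR_CAP_THETA:
        return StoddartRegion("north", -1, "4C1 cap", ("4C1",))
    if pc.theta >= 180.0 - _POLAR_CAP_THETA:
        return StoddartRegion("south", -1, "1C4 cap", ("1C4",))
    hemi = "north" if pc.theta < 90.0 else "south"
    # theta exactly 90 (equator) is charted on the northern diagram
    if pc.theta == 90.0:
        hemi = "north"
    # boundary phi values (multiples of 90) belong to the lower-phi quadrant
    phi = pc.phi % 360.0
    if phi > 0.0 and phi % 90.0 == 0.0:
        quadrant = int(phi // 90.0) - 1
    else:
        quadrant = int(phi // 90.0) % 4
    lo, hi = 90.0 * quadrant, 90.0 * (quadrant + 1)
    members = tuple(sorted(
        lbl for lbl, (t, p) in reference_conformers().items()
        if lbl not in ("4C1", "1C4")
        and ((t < 90.0) == (hemi == "north") or t == 90.0)
        and (lo < p <= hi or (p == 0.0 and quadrant == 0))
    ))
    return StoddartRegion(hemi, quadrant,
                          f"{hemi} phi [{lo:g},{hi:g}): " + "/".join(members),
                          members)


def pucker_cv(pc: PuckerCoords) -> PuckerCV:
    """Normalized Cartesian puckering coordinates (qx/Q, qy/Q).

    These are the collective variables used for ring-conformational
    free-energy landscapes; u^2 + v^2 = sin^2(theta) <= 1.
    """
    if pc.Q <= 0.0:
        raise GeometryError("pucker CVs undefined for a planar ring (Q = 0)")
    return PuckerCV(u=pc.qx / pc.Q, v=pc.qy / pc.Q)


# ---------------------------------------------------------------------------
# inverse transform (ring construction)
# ---------------------------------------------------------------------------

def inverse_cp(Q: float, theta: float, phi: float,
               radius: float = 1.46,
               labels: tuple[str, ...] = PYRANOSE_LABELS) -> RingAtoms:
    """Build a 6-ring whose Cremer-Pople coordinates are (Q, theta, phi).

    The template is a regular planar hexagon of the given circumradius (the
    default gives ~1.46 A edges, a typical pyranose bond length) to which
    the ideal out-of-plane displacement pattern

        z_j = sqrt(1/3) q2 cos(phi + 4 pi j / 6) + sqrt(1/6) q3 (-1)^j

    is applied.  Because the mean plane of the displaced ring tilts slightly,
    re-analysis reproduces (Q, theta, phi) to within ~2 degrees / 0.01 A
    rather than exactly; amplitudes above 1.2 A are chemically implausible
    and trigger a warning.
    """
    import warnings
    if Q < 0:
        raise GeometryError("Q must be nonnegative")
    if Q > 1.2:
        warnings.warn(f"puckering amplitude Q={Q:.2f} A is unphysically large",
                      stacklevel=2)
    th, ph = math.radians(theta), math.radians(phi)
    q2 = Q * math.sin(th)
    q3 = Q * math.cos(th)
    j = np.arange(6)
    # planar hexagon traversed so that the CP normal points toward +z
    ang = -2 * np.pi * j / 6
    xy = radius * np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
    z = (math.sqrt(1.0 / 3.0) * q2 * np.cos(ph + 4 * np.pi * j / 6)
         + math.sqrt(1.0 / 6.0) * q3 * (-1.0) ** j)
    pos = xy.copy()
    pos[:, 2] = z
    return RingAtoms(positions=pos, labels=labels)


def ring_mean_plane(ring: RingAtoms) -> tuple[np.ndarray, np.ndarray]:
    """(center, unit normal) of the Cremer-Pople mean plane.

    The normal is oriented so that a 4C1 pyranose has positive qz; this is
    the "above the ring" direction used for protonation geometry.
    """
    center = ring.positions.mean(axis=0)
    pos = ring.positions - center
    j = np.arange(6)
    r_sin = (pos * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    r_cos = (pos * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(r_sin, r_cos)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate ring: cannot define a mean plane")
    return center, n / norm
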