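"""Geometry of the glycosidic linkage and of acid/base approach.

Retaining beta-glucosidases protonate the glycosidic oxygen at the start
of hydrolysis.  Which lone pair of that oxygen the catalytic acid targets
defines the protonation trajectory: a lone pair lying in the plane of the
-1 sugar ring on the same side as the endocyclic O5 gives *syn*-lateral
protonation, the opposite side gives *anti*-lateral, and a lone pair
standing above (or below) the ring plane gives *perpendicular*
protonation.  This module measures the relevant torsions and distances and
classifies the approach geometry, using an idealized sp3 lone-pair model
(a geometric proxy -- no electron densities are computed).

Classification thresholds (elevation of the donor above the ring mean
plane): |elevation| >= 45 deg -> perpendicular, 30-45 deg -> intermediate,
< 30 deg -> lateral.  The thresholds are exposed so users can match other
conventions; every classification reports the raw elevation alongside.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, angle, dihedral, distance
from .pucker import RingAtoms, ring_mean_plane
from .structure import AtomNotFoundError, Structure

__all__ = [
    "LinkageType",
    "GlycosidicLinkage",
    "LonePairModel",
    "ProtonationClass",
    "ProtonationGeometry",
    "RotamerLabel",
    "StateDistances",
    "DistanceRule",
    "glycosidic_torsion",
    "lone_pairs",
    "classify_protonation",
    "hydroxymethyl_rotamer",
    "catalytic_distance",
    "state_distances",
    "PERPENDICULAR_THRESHOLD",
    "INTERMEDIATE_THRESHOLD",
]

PERPENDICULAR_THRESHOLD = 45.0  # degrees of elevation above the ring plane
INTERMEDIATE_THRESHOLD = 30.0
DONOR_RANGE_DEFAULT = 4.5       # Angstrom; beyond this the donor is out of range

_TETRAHEDRAL = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...


class LinkageType(str, enum.Enum):
    BETA_1_4 = "beta-1,4"   # cellobiose-like; acceptor carbon C4'
    BETA_1_3 = "beta-1,3"   # laminaribiose-like; acceptor carbon C3'

    @property
    def acceptor_atom(self) -> str:
        return "C4" if self is LinkageType.BETA_1_4 else "C3"


@dataclass(frozen=True)
class GlycosidicLinkage:
    """Declared (not inferred) glycosidic linkage between two residues.

    The donor ring occupies the -1 subsite; O_gly is the bridging oxygen
    (named O4 or O3 on the +1 residue in PDB carbohydrate conventions).
    """

    chain: str
    donor_res_seq: int           # -1 subsite glucosyl residue
    acceptor_res_seq: int        # +1 subsite residue
    linkage_type: LinkageType
    o_gly_name: str | None = None   # default: O4/O3 on the acceptor residue

    @property
    def bridge_atom(self) -> str:
        if self.o_gly_name is not None:
            return self.o_gly_name
        return "O4" if self.linkage_type is LinkageType.BETA_1_4 else "O3"


@dataclass(frozen=True)
class LonePairModel:
    lp1: np.ndarray          # unit vector at O_gly, on the +normal side
    lp2: np.ndarray          # unit vector, -normal side
    elevation1: float        # degrees above the donor-ring mean plane
    elevation2: float


class ProtonationClass(str, enum.Enum):
    SYN_LATERAL = "syn-lateral"
    ANTI_LATERAL = "anti-lateral"
    PERPENDICULAR_ABOVE = "perpendicular-above"
    PERPENDICULAR_BELOW = "perpendicular-below"
    INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class ProtonationGeometry:
    protonation_class: ProtonationClass
    elevation: float             # degrees, signed (+ above the oriented plane)
    side_vs_O5: str              # "same" | "opposite" | "indeterminate"
    targeted_lp: int             # 1 or 2, the nearer lone pair
    donor_distance: float        # donor to O_gly, Angstrom
    in_range: bool
    perpendicular_threshold: float = PERPENDICULAR_THRESHOLD
    intermediate_threshold: float = INTERMEDIATE_THRESHOLD


@dataclass(frozen=True)
class RotamerLabel:
    omega: float        # O5-C5-C6-O6 torsion, degrees
    omega_prime: float  # C4-C5-C6-O6 torsion, degrees
    label: str          # "gg" | "gt" | "tg" | "undefined"


@dataclass(frozen=True)
class StateDistances:
    """The five reaction-coordinate distances reported per mechanistic state.

    Order is fixed: C1-O1', C1-O5, C1-O(nucleophile), O1'-H(acid),
    O-H(acid).  Hydrogen-dependent fields are None when the structure has
    no hydrogens.
    """

    d_C1_O1prime: float
    d_C1_O5: float
    d_C1_OE441: float
    d_O1prime_H_D593: float | None
    d_OH_D593: float | None

    def as_tuple(self):
        return (self.d_C1_O1prime, self.d_C1_O5, self.d_C1_OE441,
                self.d_O1prime_H_D593, self.d_OH_D593)


class DistanceRule(str, enum.Enum):
    MIN_CARBOXYL_O_PAIR = "min-carboxyl-O-pair"
    CARBOXYL_C_TO_CARBOXYL_C = "carboxyl-C-to-carboxyl-C"
    EXPLICIT_ATOMS = "explicit-atoms"


# ---------------------------------------------------------------------------


def _ring_atoms(s: Structure, chain: str, res_seq: int) -> RingAtoms:
    names = ("O5", "C1", "C2", "C3", "C4", "C5")
    pos = np.array([s.find(chain, res_seq, n).position for n in names])
    return RingAtoms(positions=pos, labels=names)


def glycosidic_torsion(s: Structure, link: GlycosidicLinkage) -> float:
    """Signed glycosidic torsion O5-C1-O_gly-C_acceptor in degrees."""
    o5 = s.find(link.chain, link.donor_res_seq, "O5").position
    c1 = s.find(link.chain, link.donor_res_seq, "C1").position
    o_gly = s.find(link.chain, link.acceptor_res_seq, link.bridge_atom).position
    cacc = s.find(link.chain, link.acceptor_res_seq,
                  link.linkage_type.acceptor_atom).position
    return dihedral(o5, c1, o_gly, cacc)


def lone_pairs(c1: np.ndarray, o_gly: np.ndarray, acceptor_c: np.ndarray,
               ring_normal: np.ndarray | None = None) -> LonePairModel:
    """Idealized sp3 lone-pair directions at the glycosidic oxygen.

    The two lone pairs lie in the plane perpendicular to the C1-O-C plane
    that contains the external bisector of the C-O-C angle, symmetric about
    that bisector.  Their opening angle is chosen so each lone pair makes
    exactly the tetrahedral angle (109.47 deg) with both C-O bonds, which
    reduces to the half-tetrahedral construction when the C-O-C angle is
    itself tetrahedral.

    If ``ring_normal`` is given, lp1 is the lone pair on its positive side
    and the elevations are measured against the corresponding ring plane;
    otherwise elevations are relative to the C-O-C-perpendicular frame.
    """
    c1 = np.asarray(c1, float)
    o = np.asarray(o_gly, float)
    cacc = np.asarray(acceptor_c, float)
    coc = angle(c1, o, cacc)
    if not (90.0 < coc < 140.0):
        raise GeometryError(
            f"C-O-C angle {coc:.1f} deg outside the sp3-model range (90, 140)")
    b1 = c1 - o
    b2 = cacc - o
    b1 /= np.linalg.norm(b1)
    b2 /= np.linalg.norm(b2)
    bis_ext = -(b1 + b2)
    bis_ext /= np.linalg.norm(bis_ext)
    n_coc = np.cross(b1, b2)
    n_coc /= np.linalg.norm(n_coc)
    # each bond makes angle beta with the internal bisector; solve the
    # opening gamma so that cos(lp, bond) = cos(109.47) = -1/3 exactly
    beta = math.radians(coc / 2.0)
    cos_gamma = -math.cos(math.radians(_TETRAHEDRAL)) / math.cos(beta)
    cos_gamma = min(1.0, cos_gamma)
    gamma = math.acos(cos_gamma)
    lp_a = math.cos(gamma) * bis_ext + math.sin(gamma) * n_coc
    lp_b = math.cos(gamma) * bis_ext - math.sin(gamma) * n_coc

    if ring_normal is not None:
        nrm = np.asarray(ring_normal, float)
        nrm = nrm / np.linalg.norm(nrm)
        if np.dot(lp_a, nrm) < np.dot(lp_b, nrm):
            lp_a, lp_b = lp_b, lp_a
        elev = lambda v: math.degrees(math.asin(np.clip(np.dot(v, nrm), -1, 1)))
        return LonePairModel(lp1=lp_a, lp2=lp_b,
                             elevation1=elev(lp_a), elevation2=elev(lp_b))
    elev = lambda v: math.degrees(math.asin(np.clip(np.dot(v, n_coc), -1, 1)))
    return LonePairModel(lp1=lp_a, lp2=lp_b,
                         elevation1=elev(lp_a), elevation2=elev(lp_b))


def classify_protonation(
    donor_pos: np.ndarray,
    s: Structure,
    link: GlycosidicLinkage,
    perpendicular_threshold: float = PERPENDICULAR_THRESHOLD,
    intermediate_threshold: float = INTERMEDIATE_THRESHOLD,
    donor_range: float = DONOR_RANGE_DEFAULT,
) -> ProtonationGeometry:
    """Classify the acid/base approach to the glycosidic oxygen.

    Elevation is the angle between the O_gly->donor direction and the
    donor-ring Cremer-Pople mean plane, signed by the side of the oriented
    ring normal.  High elevation means the donor approaches the
    perpendicular lone pair (above or below the ring); low elevation means
    a lateral approach, split into syn/anti by whether the donor sits on
    the same in-plane side as the endocyclic O5 (exactly in the C1->O_gly
    axis plane -> indeterminate, classified intermediate).
    """
    donor = np.asarray(donor_pos, float)
    ring = _ring_atoms(s, link.chain, link.donor_res_seq)
    center, normal = ring_mean_plane(ring)
    o_gly = s.find(link.chain, link.acceptor_res_seq, link.bridge_atom).position
    c1 = s.find(link.chain, link.donor_res_seq, "C1").position
    o5 = s.find(link.chain, link.donor_res_seq, "O5").position
    cacc = s.find(link.chain, link.acceptor_res_seq,
                  link.linkage_type.acceptor_atom).position

    d = distance(donor, o_gly)
    in_range = d <= donor_range
    if not in_range:
        warnings.warn(
            f"donor is {d:.2f} A from the glycosidic oxygen "
            f"(> {donor_range:.1f} A); classification is out of range",
            stacklevel=2)

    v = donor - o_gly
    v = v / np.linalg.norm(v)
    elevation = math.degrees(math.asin(float(np.clip(np.dot(v, normal), -1, 1))))

    # in-plane side test relative to the C1->O_gly axis
    axis = o_gly - c1
    axis_inplane = axis - np.dot(axis, normal) * normal
    axis_inplane /= max(np.linalg.norm(axis_inplane), 1e-12)
    side_of = lambda p: float(np.dot(normal, np.cross(axis_inplane,
                                                      _inplane(p - o_gly, normal))))
    s_o5 = side_of(o5)
    s_donor = side_of(donor)
    if abs(s_donor) < 1e-9 or abs(s_o5) < 1e-9:
        side = "indeterminate"
    else:
        side = "same" if s_donor * s_o5 > 0 else "opposite"

    lps = lone_pairs(c1, o_gly, cacc, ring_normal=normal)
    ang1 = math.degrees(math.acos(np.clip(np.dot(v, lps.lp1), -1, 1)))
    ang2 = math.degrees(math.acos(np.clip(np.dot(v, lps.lp2), -1, 1)))
    targeted = 1 if ang1 <= ang2 else 2

    if abs(elevation) >= perpendicular_threshold:
        cls = (ProtonationClass.PERPENDICULAR_ABOVE if elevation > 0
               else ProtonationClass.PERPENDICULAR_BELOW)
    elif abs(elevation) >= intermediate_threshold or side == "indeterminate":
        cls = ProtonationClass.INTERMEDIATE
    else:
        cls = (ProtonationClass.SYN_LATERAL if side == "same"
               else ProtonationClass.ANTI_LATERAL)
    return ProtonationGeometry(
        protonation_class=cls, elevation=elevation, side_vs_O5=side,
        targeted_lp=targeted, donor_distance=d, in_range=in_range,
        perpendicular_threshold=perpendicular_threshold,
        intermediate_threshold=intermediate_threshold)


def _inplane(vec: np.ndarray, normal: np.ndarray) -> np.ndarray:
    w = vec - np.dot(vec, normal) * normal
    n = np.linalg.norm(w)
    return w / n if n > 1e-12 else w


# rotamer bins: canonical (omega, omega') pairs for the three staggered
# orientations of the C5-C6 bond in D-glucopyranose nomenclature, where
# omega = O5-C5-C6-O6 and omega' = C4-C5-C6-O6 (gauche/trans of O6 with
# respect to O5 and C4).  Windows are +/-60 degrees wide around each
# canonical value, applied to both torsions.
ROTAMER_BINS: dict[str, tuple[float, float]] = {
    "gg": (-60.0, 60.0),
    "gt": (60.0, 180.0),
    "tg": (180.0, -60.0),
}
ROTAMER_WINDOW = 60.0  # degrees half-width


def _ang_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def hydroxymethyl_rotamer(s: Structure, chain: str, res_seq: int) -> RotamerLabel:
    """gg/gt/tg label of the exocyclic hydroxymethyl of a glucosyl residue.

    Both torsions must fall in the same rotamer's window (half-width 60 deg)
    for a label; otherwise the rotamer is "undefined".  Angles are wrapped,
    so a torsion shifted by 360 degrees classifies identically.
    """
    get = lambda n: s.find(chain, res_seq, n).position
    omega = dihedral(get("O5"), get("C5"), get("C6"), get("O6"))
    omega_p = dihedral(get("C4"), get("C5"), get("C6"), get("O6"))
    label = "undefined"
    for name, (w0, wp0) in ROTAMER_BINS.items():
        if _ang_diff(omega, w0) < ROTAMER_WINDOW and _ang_diff(omega_p, wp0) < ROTAMER_WINDOW:
            label = name
            break
    return RotamerLabel(omega=omega, omega_prime=omega_p, label=label)


_CARBOXYL_O = {"OD1", "OD2", "OE1", "OE2"}
_CARBOXYL_C = {"CG", "CD"}


def catalytic_distance(
    s: Structure,
    chain_a: str, res_a: int,
    chain_b: str, res_b: int,
    rule: DistanceRule = DistanceRule.MIN_CARBOXYL_O_PAIR,
    atoms: tuple[str, str] | None = None,
) -> float:
    """Distance between the nucleophile and acid/base residues under a rule.

    min-carboxyl-O-pair (default): closest approach of the side-chain
    carboxyl/carboxamide oxygens.  carboxyl-C-to-carboxyl-C: CG/CD carbon
    distance.  explicit-atoms: the named atom pair.
    """
    ra = s.residue_atoms(chain_a, res_a)
    rb = s.residue_atoms(chain_b, res_b)
    if rule is DistanceRule.EXPLICIT_ATOMS:
        if atoms is None:
            raise GeometryError("explicit-atoms rule requires an atom-name pair")
        pa = s.find(chain_a, res_a, atoms[0]).position
        pb = s.find(chain_b, res_b, atoms[1]).position
        return distance(pa, pb)
    if rule is DistanceRule.CARBOXYL_C_TO_CARBOXYL_C:
        ca = [a for a in ra if a.name in _CARBOXYL_C]
        cb = [b for b in rb if b.name in _CARBOXYL_C]
        if not ca or not cb:
            raise AtomNotFoundError("carboxyl carbon (CG/CD) missing in a residue")
        # the outermost carboxyl carbon: CD for Glu, CG for Asp/Asn
        pick = lambda lst: next((a for a in lst if a.name == "CD"), lst[0])
        return distance(pick(ca).position, pick(cb).position)
    oa = [a for a in ra if a.name in _CARBOXYL_O]
    ob = [b for b in rb if b.name in _CARBOXYL_O]
    if not oa or not ob:
        raise AtomNotFoundError(
            "side-chain carboxyl oxygens missing; cannot apply min-carboxyl-O-pair")
    return min(distance(a.position, b.position) for a in oa for b in ob)


def state_distances(s: Structure, atom_map: dict[str, tuple[str, int, str]]
                    ) -> StateDistances:
    """The five mechanistic distances for one frame/structure.

    ``atom_map`` maps the roles 'C1', 'O1prime', 'O5', 'O_nucleophile',
    'O_acid' and optionally 'H_acid' to (chain, res_seq, atom_name).
    Hydrogen-dependent distances are None when 'H_acid' is absent.
    """
    def pos(role: str) -> np.ndarray:
        chain, seq, name = atom_map[role]
        return s.find(chain, seq, name).position

    for role in ("C1", "O1prime", "O5", "O_nucleophile", "O_acid"):
        if role not in atom_map:
            raise AtomNotFoundError(f"atom map is missing required role {role!r}")
    c1 = pos("C1")
    o1p = pos("O1prime")
    d_h1 = d_h2 = None
    if "H_acid" in atom_map:
        h = pos("H_acid")
        d_h1 = distance(o1p, h)
        d_h2 = distance(pos("O_acid"), h)
    return StateDistances(
        d_C1_O1prime=distance(c1, o1p),
        d_C1_O5=distance(c1, pos("O5")),
        d_C1_OE441=distance(c1, pos("O_nucleophile")),
        d_O1prime_H_D593=d_h1,
        d_OH_D593=d_h2,
    )
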