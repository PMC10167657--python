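"""Synthetic inputs: analytic surfaces, ideal rings, model disaccharides,
noisy kinetic data.

The true QM/MM energy surfaces of the enzymatic reaction are not
computable here; what the analysis pipeline needs is surfaces with the
right *topology* and calibrated barriers.  Surfaces are sums of negative
Gaussian wells plus a smooth quartic-hinge confinement, which keeps
energies and gradients analytic everywhere and makes barriers calibratable
by a one-dimensional search.

Two presets mirror the landscapes of glucosidase catalysis:

* ``reaction_preset`` -- the glycosylation landscape in the two
  distance-difference CVs: two adjacent reactant basins (MC, the Michaelis
  complex, and MC', the sub-state with the acid hydrogen-bonded to the
  glycosidic oxygen) at positive CV values separated by a small barrier,
  and a product basin (GEI, the glycosyl-enzyme intermediate) at negative
  CV values behind a large calibrated barrier.
* ``pucker_preset`` -- the ring-conformational landscape on the (qx/Q,
  qy/Q) disk: a single broad asymmetric minimum at the 4C1 center with a
  low shelf extending toward the 4E/4H3 direction (the itinerary toward
  the transition-state half-chair).

Geometry builders are closure-tested: re-measuring a built object with the
analysis modules recovers the generating parameters.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize

from .geometry import GeometryError, dihedral
from .pucker import (RingAtoms, inverse_cp, reference_conformers,
                     ring_mean_plane)
from .structure import AtomRecord, Structure, write_pdb
from .mechanism import LinkageType
from .kinetics import RateMeasurement

__all__ = [
    "Well",
    "ToySurfaceSpec",
    "SyntheticDisaccharideSpec",
    "MMDataSpec",
    "make_surface",
    "double_well_1d",
    "reaction_preset",
    "pucker_preset",
    "build_ring",
    "build_disaccharide",
    "noisy_mm_data",
]


# ---------------------------------------------------------------------------
# analytic surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Well:
    center: tuple[float, ...]
    depth: float                    # kcal/mol, > 0 (well depth)
    widths: tuple[float, ...]       # per-dimension sigma
    angle: float = 0.0              # degrees; 2-D rotation of the width axes

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("well depth must be positive")
        if any(w <= 0 for w in self.widths):
            raise ValueError("well widths must be positive")


@dataclass(frozen=True)
class ToySurfaceSpec:
    """Sum of negative Gaussian wells + quartic-hinge radial confinement.

    The confinement is k * max(0, (r - r0)/w)^4 about ``confine_center``:
    zero inside radius r0, rising smoothly (C3) outside, so walkers cannot
    escape to infinity.
    """

    wells: tuple[Well, ...]
    dimension: int
    confine_radius: float = 1.9
    confine_k: float = 30.0
    confine_width: float = 0.3
    confine_center: tuple[float, ...] | None = None
    labels: dict = field(default_factory=dict)   # basin name -> CV point

    def __post_init__(self):
        if not self.wells:
            raise ValueError("need at least one well")
        for w in self.wells:
            if len(w.center) != self.dimension or len(w.widths) != self.dimension:
                raise ValueError("well dimension mismatch")


def _rotation2(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def make_surface(spec: ToySurfaceSpec, shift_min_to_zero: bool = True,
                 check_merging: bool = False
                 ) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """Compile a spec into ``surface(x) -> (energy, gradient)``.

    With ``shift_min_to_zero`` the global minimum (located numerically from
    the deepest well centers) is subtracted, so min E = 0.  With
    ``check_merging`` each well-center pair is probed along its connecting
    segment; pairs with no interior energy maximum have merged into one
    minimum and are reported in a warning.
    """
    dim = spec.dimension
    centers = np.array([w.center for w in spec.wells])
    depths = np.array([w.depth for w in spec.wells])
    inv_w = 1.0 / np.array([w.widths for w in spec.wells])
    rots = [(_rotation2(w.angle) if (dim == 2 and w.angle) else None)
            for w in spec.wells]
    cc = (np.zeros(dim) if spec.confine_center is None
          else np.asarray(spec.confine_center, float))
    r0, kq, wq = spec.confine_radius, spec.confine_k, spec.confine_width

    def raw(x: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.atleast_1d(np.asarray(x, float))
        e = 0.0
        g = np.zeros(dim)
        for c, d, iw, rot in zip(centers, depths, inv_w, rots):
            xi = x - c
            if rot is not None:
                xi = rot.T @ xi
            u = xi * iw
            expo = math.exp(-0.5 * float(u @ u))
            e -= d * expo
            gl = d * expo * (u * iw)
            g += rot @ gl if rot is not None else gl
        rvec = x - cc
        r = float(np.linalg.norm(rvec))
        if r > r0:
            t = (r - r0) / wq
            e += kq * t**4
            g += (4.0 * kq * t**3 / (wq * max(r, 1e-12))) * rvec
        return e, g

    offset = 0.0
    if shift_min_to_zero:
        best = math.inf
        for c in centers[np.argsort(-depths)][:3]:
            res = minimize(lambda x: raw(x)[0], c, jac=lambda x: raw(x)[1],
                           method="BFGS")
            best = min(best, float(res.fun))
        offset = best

    if check_merging:
        merged = []
        for i in range(len(spec.wells)):
            for j in range(i + 1, len(spec.wells)):
                ts = np.linspace(0.0, 1.0, 101)[1:-1]
                seg = centers[i] + np.outer(ts, centers[j] - centers[i])
                evals = np.array([raw(p)[0] for p in seg])
                e_ends = max(raw(centers[i])[0], raw(centers[j])[0])
                if evals.max() <= e_ends + 1e-9:
                    merged.append((i, j))
        if merged:
            warnings.warn(f"wells merged into single minima for pairs {merged}",
                          stacklevel=2)

    def surface(x):
        e, g = raw(x)
        return e - offset, g

    surface.spec = spec
    return surface


def double_well_1d(barrier: float, half_separation: float = 1.0
                   ) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """Symmetric quartic double well E(x) = b ((x/a)^2 - 1)^2.

    Minima at +/-a with E = 0, analytic saddle of height ``barrier`` at
    x = 0.  The workhorse surface for validating metadynamics
    reconstruction and committor estimates against known answers.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    a = half_separation

    def surface(x):
        x = np.atleast_1d(np.asarray(x, float))
        u = (x[0] / a) ** 2 - 1.0
        e = barrier * u * u
        g = np.array([4.0 * barrier * u * x[0] / (a * a)])
        return float(e), g

    surface.barrier = barrier
    surface.minima = (-a, a)
    return surface


# ---------------------------------------------------------------------------
# reaction preset (glycosylation landscape)
# ---------------------------------------------------------------------------

_MC = (1.14, 1.14)
_MCP = (0.5, 0.5)
_BRIDGE = (0.82, 0.82)
_GEI = (-0.9, -1.0)


def _reaction_spec(scale: float) -> ToySurfaceSpec:
    wells = (
        Well(center=_MC, depth=1.00 * scale, widths=(0.28, 0.28)),
        Well(center=_MCP, depth=1.05 * scale, widths=(0.28, 0.28)),
        # shallow connector between MC and MC' -> low inter-reactant saddle
        Well(center=_BRIDGE, depth=0.45 * scale, widths=(0.28, 0.28)),
        Well(center=_GEI, depth=1.05 * scale + 3.0, widths=(0.42, 0.42)),
    )
    return ToySurfaceSpec(
        wells=wells, dimension=2,
        confine_radius=1.9, confine_k=30.0, confine_width=0.3,
        labels={"MC": _MC, "MC'": _MCP, "GEI": _GEI},
    )


def _line_barrier(surface, a, b, n: int = 2001) -> float:
    """Barrier from basin at ``a`` to basin at ``b``: maximum energy along the
    straight segment minus the locally minimized energy near ``a``.

    Valid when the relevant saddle lies on the segment, which holds here
    because the flanking wells are isotropic Gaussians (the stationary
    point between two isotropic Gaussians lies on the line joining their
    centers; the distant wells and the confinement contribute negligibly).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ts = np.linspace(0.0, 1.0, n)
    emax = max(surface(a + t * (b - a))[0] for t in ts)
    res = minimize(lambda x: surface(x)[0], a, jac=lambda x: surface(x)[1],
                   method="BFGS")
    return float(emax - res.fun)


def reaction_preset(target_barrier: float = 17.6,
                    calibration_tol: float = 0.02) -> ToySurfaceSpec:
    """Three-basin glycosylation-landscape preset with a calibrated barrier.

    Both CVs are positive in the reactant basins (MC, MC') and negative at
    the product (GEI), matching the sign convention of distance-difference
    CVs for bond exchange.  The overall depth scale of the reactant wells
    is calibrated by a 1-D line search (Brent root finding on the
    straight-segment barrier MC' -> GEI) so that the escape barrier equals
    ``target_barrier``; the MC <-> MC' barrier stays a small fixed fraction
    (~12%) of the scale.  The returned spec carries the achieved barrier in
    ``labels['calibrated_barrier']``.
    """
    if target_barrier <= 0:
        raise ValueError("target_barrier must be positive")

    def f(scale: float) -> float:
        surf = make_surface(_reaction_spec(scale), shift_min_to_zero=False)
        return _line_barrier(surf, _MCP, _GEI) - target_barrier

    lo, hi = 0.3 * target_barrier, 1.5 * target_barrier
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            f"barrier calibration failed: f({lo})={flo:.3f}, f({hi})={fhi:.3f}")
    scale = brentq(f, lo, hi, xtol=1e-4)
    spec = _reaction_spec(scale)
    achieved = f(scale) + target_barrier
    if abs(achieved - target_barrier) > calibration_tol:
        raise RuntimeError(
            f"calibration landed at {achieved:.4f}, target {target_barrier}")
    spec.labels["calibrated_barrier"] = achieved
    spec.labels["scale"] = scale
    return spec


# ---------------------------------------------------------------------------
# pucker preset (ring-conformational landscape on the u-v disk)
# ---------------------------------------------------------------------------

def pucker_preset(shelf_offset: float = 3.0, depth: float = 8.0) -> ToySurfaceSpec:
    """Single broad asymmetric well on the (u, v) = (qx/Q, qy/Q) disk.

    The global minimum sits at the 4C1 projection (0, 0).  The well is
    elongated toward the 4E/4H3 longitude (phi ~ 225 degrees), and its
    long-axis width is solved analytically so that the energy at the 4E
    shelf point (radius sin(54.74 deg) along that longitude) lies exactly
    ``shelf_offset`` kcal/mol above the minimum.  The confinement keeps
    dynamics inside the physical unit disk.
    """
    if not 0 < shelf_offset < depth:
        raise ValueError("need 0 < shelf_offset < depth")
    ref = reference_conformers()
    th_e, phi_e = ref["4E"]
    th_h, phi_h = ref["4H3"]
    phi_shelf = 0.5 * (phi_e + phi_h)          # between 4H3 and 4E
    rho_shelf = math.sin(math.radians(th_e))   # radius of the E tropic, ~0.816
    # depth * (1 - exp(-rho^2 / 2 sigma^2)) = shelf_offset
    sigma_long = rho_shelf / math.sqrt(
        2.0 * math.log(depth / (depth - shelf_offset)))
    spec = ToySurfaceSpec(
        wells=(Well(center=(0.0, 0.0), depth=depth,
                    widths=(sigma_long, 0.45), angle=phi_shelf),),
        dimension=2,
        confine_radius=0.98, confine_k=200.0, confine_width=0.15,
        labels={
            "4C1": (0.0, 0.0),
            "shelf": (rho_shelf * math.cos(math.radians(phi_shelf)),
                      rho_shelf * math.sin(math.radians(phi_shelf))),
            "shelf_offset": shelf_offset,
        },
    )
    return spec


# ---------------------------------------------------------------------------
# ring and disaccharide builders
# ---------------------------------------------------------------------------

def build_ring(conformer: str | tuple[float, float, float],
               Q: float = 0.57) -> RingAtoms:
    """Pyranose ring at a prescribed pucker.

    ``conformer`` is either a canonical label ("4C1", "4H3", "1S3", ...)
    whose reference (theta, phi) is used with amplitude ``Q``, or an
    explicit (Q, theta, phi) triple.
    """
    if isinstance(conformer, str):
        table = reference_conformers()
        if conformer not in table:
            raise GeometryError(f"unknown conformer label {conformer!r}")
        theta, phi = table[conformer]
        return inverse_cp(Q, theta, phi)
    q, theta, phi = conformer
    return inverse_cp(q, theta, phi)


def _place_atom(a, b, c, bond: float, ang_deg: float, torsion_deg: float
                ) -> np.ndarray:
    """NeRF atom placement: position d with |c-d| = bond, angle(b,c,d) =
    ang_deg and dihedral(a,b,c,d) = torsion_deg."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    th = math.radians(ang_deg)
    ph = math.radians(torsion_deg)
    d_local = bond * np.array([-math.cos(th),
                               math.sin(th) * math.cos(ph),
                               math.sin(th) * math.sin(ph)])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


@dataclass(frozen=True)
class SyntheticDisaccharideSpec:
    linkage_type: LinkageType = LinkageType.BETA_1_4
    glycosidic_torsion: float = -77.2      # degrees, O5-C1-O_gly-C_acceptor
    omega: float = 60.0                    # O5-C5-C6-O6, gt default
    donor_class: str = "perpendicular"     # perpendicular | syn | anti | custom
    donor_direction: tuple[float, float, float] | None = None  # for custom
    donor_distance: float = 2.9            # donor atom to O_gly, Angstrom
    donor_pucker: str | tuple = "4C1"
    acceptor_pucker: str | tuple = "4C1"
    pucker_amplitude: float = 0.57


def build_disaccharide(spec: SyntheticDisaccharideSpec,
                       path: str | Path | None = None) -> Structure:
    """Minimal synthetic disaccharide + catalytic-proxy atoms.

    Atoms: the -1 (donor) glucosyl ring with its C6/O6 arm, the bridging
    glycosidic oxygen, the +1 (acceptor) ring, one proxy acid/base donor
    atom (ASN ND2 analog, residue 593) placed per ``donor_class``, and one
    proxy nucleophile oxygen (GLU OE1 analog, residue 441) below the
    anomeric carbon.  Re-measuring the structure with the mechanism module
    reproduces the generating torsion (within 0.5 deg), rotamer label and
    protonation class exactly -- the builder's closure contract.

    If ``path`` is given the structure is also written as a PDB fixture
    with a JSON parameter sidecar at ``path + '.json'``.
    """
    ring = build_ring(spec.donor_pucker, Q=spec.pucker_amplitude)
    names = dict(zip(ring.labels, ring.positions))
    center, normal = ring_mean_plane(ring)

    # exocyclic C6 on C5: the tetrahedral direction not used by the ring,
    # chosen on the branch that gives omega' = omega + 120 (D-gluco sense)
    o5, c1, c4, c5 = names["O5"], names["C1"], names["C4"], names["C5"]
    u1 = (o5 - c5) / np.linalg.norm(o5 - c5)
    u2 = (c4 - c5) / np.linalg.norm(c4 - c5)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    delta = math.radians(54.75)
    best = None
    for sign in (1.0, -1.0):
        c6 = c5 + 1.52 * (math.cos(delta) * bis + sign * math.sin(delta) * perp)
        o6 = _place_atom(o5, c5, c6, 1.43, 109.5, spec.omega)
        w = dihedral(o5, c5, c6, o6)
        wp = dihedral(c4, c5, c6, o6)
        if abs((wp - w - 120.0 + 180.0) % 360.0 - 180.0) < 25.0:
            best = (c6, o6)
            break
    if best is None:   # fall back to the first branch
        c6 = c5 + 1.52 * (math.cos(delta) * bis + math.sin(delta) * perp)
        o6 = _place_atom(o5, c5, c6, 1.43, 109.5, spec.omega)
        best = (c6, o6)
    c6, o6 = best

    # glycosidic oxygen on C1 (roughly equatorial for a beta anomer) and
    # the acceptor carbon at the prescribed glycosidic torsion
    o_gly = _place_atom(c5, o5, c1, 1.41, 109.0, 180.0)
    c_acc = _place_atom(o5, c1, o_gly, 1.43, 117.0, spec.glycosidic_torsion)

    # acceptor ring: template ring rigidly placed so its linkage carbon
    # lands on c_acc, ring center pointing away from the donor ring
    acc_ring = build_ring(spec.acceptor_pucker, Q=spec.pucker_amplitude)
    acc_names = list(acc_ring.labels)
    link_atom = spec.linkage_type.acceptor_atom          # "C4" or "C3"
    t_pos = acc_ring.positions
    t_center = t_pos.mean(axis=0)
    t_link = t_pos[acc_names.index(link_atom)]
    u = t_link - t_center
    r_link = np.linalg.norm(u)
    u /= r_link
    w_dir = c_acc - o_gly          # continue the O_gly -> C bond direction
    w_dir /= np.linalg.norm(w_dir)
    existing = np.vstack([ring.positions, c6, o6, o_gly])

    def placed(rot_about_w: float) -> np.ndarray:
        R1 = _rotation_between(u, w_dir)
        Rw = _axis_rotation(w_dir, rot_about_w)
        new_center = c_acc - r_link * w_dir
        return new_center + (Rw @ R1 @ (t_pos - t_center).T).T

    best_pos, best_clear = None, -1.0
    for ang in np.linspace(0.0, 360.0, 24, endpoint=False):
        cand = placed(ang)
        others = np.delete(cand, acc_names.index(link_atom), axis=0)
        clear = min(np.linalg.norm(others[:, None, :] - existing[None, :, :],
                                   axis=2).min(),
                    np.linalg.norm(others - o_gly, axis=1).min())
        if clear > best_clear:
            best_clear, best_pos = clear, cand
    if best_clear < 1.0:
        raise GeometryError(
            f"acceptor ring clashes with donor (min distance {best_clear:.2f} A)")
    acc_positions = best_pos

    # proxy acid/base donor atom
    axis = o_gly - c1
    axis_ip = axis - np.dot(axis, normal) * normal
    axis_ip /= np.linalg.norm(axis_ip)
    lateral = np.cross(normal, axis_ip)          # in-plane, perpendicular to axis
    s_o5 = float(np.dot(lateral, o5 - o_gly))
    syn_dir = lateral if s_o5 > 0 else -lateral
    if spec.donor_class == "perpendicular":
        d_dir = normal
    elif spec.donor_class == "syn":
        d_dir = syn_dir
    elif spec.donor_class == "anti":
        d_dir = -syn_dir
    elif spec.donor_class == "custom":
        if spec.donor_direction is None:
            raise GeometryError("custom donor class needs donor_direction")
        d_dir = np.asarray(spec.donor_direction, float)
        d_dir = d_dir / np.linalg.norm(d_dir)
    else:
        raise GeometryError(f"unknown donor class {spec.donor_class!r}")
    donor_pos = o_gly + spec.donor_distance * d_dir

    # proxy nucleophile oxygen poised below the anomeric carbon
    nuc_pos = c1 - 3.2 * normal

    bridge_name = "O4" if spec.linkage_type is LinkageType.BETA_1_4 else "O3"
    atoms: list[AtomRecord] = []
    serial = 1

    def add(name, pos, res_name, res_seq, element, het):
        nonlocal serial
        atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                alt_loc="", res_name=res_name, res_seq=res_seq,
                                chain="A", position=np.asarray(pos, float),
                                occupancy=1.0, het=het))
        serial += 1

    for nm in ring.labels:
        add(nm, names[nm], "BGC", 1, "O" if nm.startswith("O") else "C", True)
    add("C6", c6, "BGC", 1, "C", True)
    add("O6", o6, "BGC", 1, "O", True)
    add(bridge_name, o_gly, "BGC", 2, "O", True)
    for nm, pos in zip(acc_names, acc_positions):
        if nm == link_atom:
            pos = c_acc     # exact linkage position
        add(nm, pos, "BGC", 2, "O" if nm.startswith("O") else "C", True)
    add("ND2", donor_pos, "ASN", 593, "N", False)
    add("OE1", nuc_pos, "GLU", 441, "O", False)

    # clash guard over the full atom set (bonded pairs excluded by the
    # 1.0 A criterion: bonds here are all >= 1.4 A)
    allpos = np.array([a.position for a in atoms])
    dmat = np.linalg.norm(allpos[:, None] - allpos[None, :], axis=2)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < 1.0:
        raise GeometryError(f"atom clash: min distance {dmat.min():.2f} A")

    st = Structure(atoms=atoms, identifier="synthetic-disaccharide",
                   source_format="builder")
    if path is not None:
        path = Path(path)
        write_pdb(st, path)
        sidecar = {
            "linkage_type": spec.linkage_type.value,
            "glycosidic_torsion": spec.glycosidic_torsion,
            "omega": spec.omega,
            "donor_class": spec.donor_class,
            "donor_distance": spec.donor_distance,
            "donor_pucker": str(spec.donor_pucker),
            "acceptor_pucker": str(spec.acceptor_pucker),
            "pucker_amplitude": spec.pucker_amplitude,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return st


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u to unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180-degree flip about any axis perpendicular to u
        axis = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        return _axis_rotation_mat(axis, math.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    return _axis_rotation_mat(axis, math.atan2(s, c))


def _axis_rotation_mat(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    return _axis_rotation_mat(axis, math.radians(angle_deg))


# ---------------------------------------------------------------------------
# kinetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMDataSpec:
    Km: float                       # mM
    kcat: float                     # 1/s
    concentrations: tuple[float, ...]   # mM
    noise_sigma: float = 0.0        # relative (multiplicative) noise
    seed: int = 0


def noisy_mm_data(spec: MMDataSpec) -> list[RateMeasurement]:
    """Michaelis-Menten velocities with multiplicative Gaussian noise,
    v = kcat S / (Km + S) * (1 + eps), eps ~ N(0, sigma); seeded."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for s in spec.concentrations:
        v = spec.kcat * s / (spec.Km + s)
        if spec.noise_sigma > 0:
            v *= 1.0 + rng.normal(0.0, spec.noise_sigma)
        out.append(RateMeasurement(substrate_conc=s, velocity=max(v, 0.0)))
    return out
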