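"""Linkage geometry, protonation classification, rotamers, distances."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glycomech.geometry import GeometryError
from glycomech.mechanism import (DistanceRule, GlycosidicLinkage, LinkageType,
                                 ProtonationClass, catalytic_distance,
                                 classify_protonation, glycosidic_torsion,
                                 hydroxymethyl_rotamer, lone_pairs,
                                 state_distances)
from glycomech.structure import AtomNotFoundError, AtomRecord, Structure
from glycomech.synthetic import SyntheticDisaccharideSpec, build_disaccharide

from conftest import random_rigid_transform

TETRA = math.degrees(math.acos(-1.0 / 3.0))


class TestGlycosidicTorsion:
    @pytest.mark.parametrize("target", [-77.2, -105.4, -60.0, 45.0])
    def test_builder_closure(self, target):
        s = build_disaccharide(SyntheticDisaccharideSpec(
            glycosidic_torsion=target))
        link = GlycosidicLinkage(chain="A", donor_res_seq=1,
                                 acceptor_res_seq=2,
                                 linkage_type=LinkageType.BETA_1_4)
        assert glycosidic_torsion(s, link) == pytest.approx(target, abs=0.5)

    def test_beta13_uses_o3_bridge(self):
        s = build_disaccharide(SyntheticDisaccharideSpec(
            linkage_type=LinkageType.BETA_1_3, glycosidic_torsion=-105.4))
        link = GlycosidicLinkage(chain="A", donor_res_seq=1,
                                 acceptor_res_seq=2,
                                 linkage_type=LinkageType.BETA_1_3)
        assert link.bridge_atom == "O3"
        assert glycosidic_torsion(s, link) == pytest.approx(-105.4, abs=0.5)

    def test_missing_atom_raises(self, disaccharide):
        bad = GlycosidicLinkage(chain="A", donor_res_seq=1,
                                acceptor_res_seq=99,
                                linkage_type=LinkageType.BETA_1_4)
        with pytest.raises(AtomNotFoundError):
            glycosidic_torsion(disaccharide, bad)


class TestLonePairs:
    @staticmethod
    def _coc(angle_deg, rng=None):
        """Symmetric C-O-C geometry in the xy-plane."""
        half = math.radians(angle_deg / 2)
        o = np.zeros(3)
        c1 = 1.4 * np.array([math.cos(half), math.sin(half), 0.0])
        c2 = 1.4 * np.array([math.cos(half), -math.sin(half), 0.0])
        return c1, o, c2

    def test_symmetric_about_plane(self):
        c1, o, c2 = self._coc(112.0)
        lp = lone_pairs(c1, o, c2)
        assert abs(lp.lp1[2]) == pytest.approx(abs(lp.lp2[2]), abs=1e-9)
        assert np.allclose(lp.lp1[:2], lp.lp2[:2], atol=1e-9)
        assert np.linalg.norm(lp.lp1) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("coc_angle", [100.0, TETRA, 117.0, 130.0])
    def test_tetrahedral_angle_to_both_bonds(self, coc_angle):
        c1, o, c2 = self._coc(coc_angle)
        lp = lone_pairs(c1, o, c2)
        b1 = (c1 - o) / np.linalg.norm(c1 - o)
        b2 = (c2 - o) / np.linalg.norm(c2 - o)
        for v in (lp.lp1, lp.lp2):
            for b in (b1, b2):
                ang = math.degrees(math.acos(np.clip(np.dot(v, b), -1, 1)))
                assert ang == pytest.approx(TETRA, abs=0.1)

    @given(st.integers(0, 10**6))
    def test_rotation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        c1, o, c2 = self._coc(rng.uniform(95, 135))
        lp0 = lone_pairs(c1, o, c2)
        R, t = random_rigid_transform(rng)
        lp1 = lone_pairs(c1 @ R.T + t, o @ R.T + t, c2 @ R.T + t)
        assert np.allclose(lp1.lp1, R @ lp0.lp1, atol=1e-9) or \
            np.allclose(lp1.lp1, R @ lp0.lp2, atol=1e-9)

    def test_near_linear_raises(self):
        c1, o, c2 = self._coc(160.0)
        with pytest.raises(GeometryError):
            lone_pairs(c1, o, c2)


def _donor_variant(donor_class, **kwargs):
    s = build_disaccharide(SyntheticDisaccharideSpec(donor_class=donor_class,
                                                     **kwargs))
    link = GlycosidicLinkage(chain="A", donor_res_seq=1, acceptor_res_seq=2,
                             linkage_type=kwargs.get("linkage_type",
                                                     LinkageType.BETA_1_4))
    donor = s.find("A", 593, "ND2").position
    return s, link, donor


class TestProtonationClass:
    @pytest.mark.parametrize("donor_class,expected", [
        ("perpendicular", ProtonationClass.PERPENDICULAR_ABOVE),
        ("syn", ProtonationClass.SYN_LATERAL),
        ("anti", ProtonationClass.ANTI_LATERAL),
    ])
    def test_constructed_classes(self, donor_class, expected):
        s, link, donor = _donor_variant(donor_class)
        got = classify_protonation(donor, s, link)
        assert got.protonation_class is expected

    def test_reflection_flips_above_to_below(self):
        # a donor placed below the ring plane mirrors the perpendicular class
        s, link, _ = _donor_variant("perpendicular")
        from glycomech.pucker import RingAtoms, ring_mean_plane
        ring = RingAtoms(positions=np.array(
            [s.find("A", 1, n).position
             for n in ("O5", "C1", "C2", "C3", "C4", "C5")]))
        center, normal = ring_mean_plane(ring)
        o_gly = s.find("A", 2, "O4").position
        below = o_gly - 2.9 * normal
        got = classify_protonation(below, s, link)
        assert got.protonation_class is ProtonationClass.PERPENDICULAR_BELOW
        assert got.elevation == pytest.approx(-90.0, abs=1e-6)

    def test_intermediate_band(self):
        # donor at 37 degrees elevation: between lateral and perpendicular
        s, link, _ = _donor_variant("perpendicular")
        from glycomech.pucker import RingAtoms, ring_mean_plane
        ring = RingAtoms(positions=np.array(
            [s.find("A", 1, n).position
             for n in ("O5", "C1", "C2", "C3", "C4", "C5")]))
        _, normal = ring_mean_plane(ring)
        o_gly = s.find("A", 2, "O4").position
        c1 = s.find("A", 1, "C1").position
        axis = o_gly - c1
        lateral = axis - np.dot(axis, normal) * normal
        lateral /= np.linalg.norm(lateral)
        elev = math.radians(37.0)
        donor = o_gly + 2.9 * (math.cos(elev) * lateral + math.sin(elev) * normal)
        got = classify_protonation(donor, s, link)
        assert got.protonation_class is ProtonationClass.INTERMEDIATE
        assert got.elevation == pytest.approx(37.0, abs=1.0)

    def test_out_of_range_donor_warns(self):
        s, link, _ = _donor_variant("perpendicular")
        far = s.find("A", 2, "O4").position + np.array([0, 0, 8.0])
        with pytest.warns(UserWarning, match="out of range"):
            got = classify_protonation(far, s, link)
        assert not got.in_range

    def test_donor_along_lone_pair_targets_it(self):
        from glycomech.mechanism import lone_pairs as lp_model
        from glycomech.pucker import RingAtoms, ring_mean_plane
        s, link, _ = _donor_variant("perpendicular")
        ring = RingAtoms(positions=np.array(
            [s.find("A", 1, n).position
             for n in ("O5", "C1", "C2", "C3", "C4", "C5")]))
        _, normal = ring_mean_plane(ring)
        o_gly = s.find("A", 2, "O4").position
        c1 = s.find("A", 1, "C1").position
        cacc = s.find("A", 2, "C4").position
        lps = lp_model(c1, o_gly, cacc, ring_normal=normal)
        for which, vec in ((1, lps.lp1), (2, lps.lp2)):
            got = classify_protonation(o_gly + 2.9 * vec, s, link)
            assert got.targeted_lp == which


class TestRotamer:
    @pytest.mark.parametrize("omega,expected", [
        (60.0, "gt"), (-60.0, "gg"), (180.0, "tg"),
        (60.0 + 360.0, "gt"),               # angle wrap
        (55.0, "gt"), (-70.0, "gg"),
    ])
    def test_builder_closure(self, omega, expected):
        s = build_disaccharide(SyntheticDisaccharideSpec(omega=omega))
        got = hydroxymethyl_rotamer(s, "A", 1)
        assert got.label == expected

    def test_canonical_windows_partition(self):
        # every omega within 60 degrees of a canonical value maps to
        # exactly one label (the torus windows do not overlap)
        for omega in np.arange(-180.0, 180.0, 7.0):
            s = build_disaccharide(SyntheticDisaccharideSpec(omega=float(omega)))
            got = hydroxymethyl_rotamer(s, "A", 1)
            dists = {lab: abs((omega - w + 180) % 360 - 180)
                     for lab, w in (("gg", -60), ("gt", 60), ("tg", 180))}
            nearest = min(dists, key=dists.get)
            if dists[nearest] < 55.0:   # away from window edges
                assert got.label == nearest

    def test_missing_arm_raises(self):
        s = build_disaccharide(SyntheticDisaccharideSpec())
        with pytest.raises(AtomNotFoundError):
            hydroxymethyl_rotamer(s, "A", 2)   # acceptor has no C6/O6 arm


def _residue(res_name, res_seq, atom_positions):
    return [AtomRecord(serial=i + 1 + 10 * res_seq, name=n, element=n[0],
                       alt_loc="", res_name=res_name, res_seq=res_seq,
                       chain="A", position=np.asarray(p, float))
            for i, (n, p) in enumerate(atom_positions.items())]


class TestCatalyticDistance:
    def test_single_oxygen_pair(self):
        st = Structure(atoms=_residue("GLU", 441, {"OE1": (0, 0, 0)})
                       + _residue("ASP", 593, {"OD1": (5, 0, 0)}))
        d = catalytic_distance(st, "A", 441, "A", 593)
        assert d == pytest.approx(5.0)

    def test_min_over_oxygen_pairs(self):
        st = Structure(atoms=_residue("GLU", 441, {"OE1": (0, 0, 0),
                                                   "OE2": (1, 0, 0)})
                       + _residue("ASP", 593, {"OD1": (5, 0, 0),
                                               "OD2": (9, 0, 0)}))
        assert catalytic_distance(st, "A", 441, "A", 593) == pytest.approx(4.0)

    def test_explicit_atoms_delegates_to_distance(self):
        from glycomech.geometry import distance
        st = Structure(atoms=_residue("GLU", 441, {"OE1": (0, 0, 0),
                                                   "CD": (0.5, 0, 0)})
                       + _residue("ASP", 593, {"OD1": (5, 0, 0),
                                               "CG": (6, 0, 0)}))
        d = catalytic_distance(st, "A", 441, "A", 593,
                               rule=DistanceRule.EXPLICIT_ATOMS,
                               atoms=("CD", "CG"))
        assert d == distance(st.find("A", 441, "CD").position,
                             st.find("A", 593, "CG").position)

    def test_carboxyl_carbon_rule(self):
        st = Structure(atoms=_residue("GLU", 441, {"CD": (0, 0, 0)})
                       + _residue("ASP", 593, {"CG": (7, 0, 0)}))
        d = catalytic_distance(st, "A", 441, "A", 593,
                               rule=DistanceRule.CARBOXYL_C_TO_CARBOXYL_C)
        assert d == pytest.approx(7.0)

    def test_missing_side_chain_raises(self):
        st = Structure(atoms=_residue("GLY", 441, {"CA": (0, 0, 0)})
                       + _residue("ASP", 593, {"OD1": (5, 0, 0)}))
        with pytest.raises(AtomNotFoundError):
            catalytic_distance(st, "A", 441, "A", 593)


class TestStateDistances:
    def _frame(self, d_c1_o1=1.46):
        atoms = (_residue("BGC", 1, {"C1": (0, 0, 0), "O5": (1.45, 0, 0)})
                 + _residue("BGC", 2, {"O4": (0, d_c1_o1, 0)})
                 + _residue("GLU", 441, {"OE1": (0, 0, -3.26)})
                 + _residue("ASP", 593, {"OD2": (0, 3.0, 2.0),
                                         "HD2": (0, 2.5, 1.2)}))
        return Structure(atoms=atoms)

    AMAP = {"C1": ("A", 1, "C1"), "O5": ("A", 1, "O5"),
            "O1prime": ("A", 2, "O4"), "O_nucleophile": ("A", 441, "OE1"),
            "O_acid": ("A", 593, "OD2"), "H_acid": ("A", 593, "HD2")}

    def test_constructed_values(self):
        sd = state_distances(self._frame(1.46), self.AMAP)
        assert sd.d_C1_O1prime == pytest.approx(1.46)
        assert sd.d_C1_O5 == pytest.approx(1.45)
        assert sd.d_C1_OE441 == pytest.approx(3.26)

    def test_covalent_intermediate_geometry(self):
        atoms = (_residue("BGC", 1, {"C1": (0, 0, 0), "O5": (1.35, 0, 0)})
                 + _residue("BGC", 2, {"O4": (0, 3.33, 0)})
                 + _residue("GLU", 441, {"OE1": (0, 0, -1.70)})
                 + _residue("ASP", 593, {"OD2": (0, 3, 2)}))
        amap = dict(self.AMAP)
        amap.pop("H_acid")
        sd = state_distances(Structure(atoms=atoms), amap)
        assert sd.d_C1_OE441 < 1.8
        assert sd.d_O1prime_H_D593 is None and sd.d_OH_D593 is None

    def test_unrelated_atoms_do_not_matter(self):
        base = state_distances(self._frame(), self.AMAP)
        noisy = self._frame()
        noisy.atoms.extend(_residue("HOH", 900, {"O": (9, 9, 9)}))
        redone = state_distances(Structure(atoms=noisy.atoms), self.AMAP)
        assert base.as_tuple() == redone.as_tuple()

    def test_missing_role_raises(self):
        amap = dict(self.AMAP)
        amap.pop("C1")
        with pytest.raises(AtomNotFoundError):
            state_distances(self._frame(), amap)


class TestRigidInvariance:
    def test_classification_invariant_under_rigid_motion(self, rng):
        spec = SyntheticDisaccharideSpec(donor_class="perpendicular")
        s = build_disaccharide(spec)
        link = GlycosidicLinkage(chain="A", donor_res_seq=1,
                                 acceptor_res_seq=2,
                                 linkage_type=LinkageType.BETA_1_4)
        ref_tor = glycosidic_torsion(s, link)
        ref_cls = classify_protonation(s.find("A", 593, "ND2").position, s, link)
        R, t = random_rigid_transform(rng)
        moved = Structure(atoms=[
            AtomRecord(serial=a.serial, name=a.name, element=a.element,
                       alt_loc=a.alt_loc, res_name=a.res_name,
                       res_seq=a.res_seq, chain=a.chain,
                       position=a.position @ R.T + t, occupancy=a.occupancy,
                       het=a.het)
            for a in s.atoms])
        assert glycosidic_torsion(moved, link) == pytest.approx(ref_tor, abs=1e-8)
        got = classify_protonation(moved.find("A", 593, "ND2").position,
                                   moved, link)
        assert got.protonation_class is ref_cls.protonation_class
        assert got.elevation == pytest.approx(ref_cls.elevation, abs=1e-6)
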