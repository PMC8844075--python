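"""Displacements, axes, rotamers, contacts, distances, insertion depth."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as hst
from scipy.spatial.transform import Rotation

from pocketframe.errors import InputError
from pocketframe.membrane_frame import RigidTransform, apply_transform
from pocketframe.state_compare import (ContactCriteria, ca_displacements,
                                       chi1_rotamer, classify_chi1,
                                       compare_states, detect_contacts,
                                       dihedral_angle, helix_axis,
                                       insertion_depth, min_distance, tilt_angle)
from pocketframe.structure_io import AtomRecord, Selector, Structure, select_atoms
from pocketframe.synthetic_structures import (BundleSpec, Perturbation,
                                              make_bundle, make_ideal_helix,
                                              make_peptide, perturb_bundle,
                                              place_atom)
from pocketframe.tm_boundary import PocketBounds

from conftest import outward_unit


def _atom(name, element, pos, resname="GLY", resnum=1, chain="A"):
    return AtomRecord(chain_id=chain, residue_number=resnum, insertion_code="",
                      residue_name=resname, atom_name=name, element=element,
                      position=pos)


class TestDisplacements:
    def test_structure_vs_itself_all_zero(self, default_bundle):
        st, _, _, _ = default_bundle
        d = ca_displacements(st, st)
        assert max(d.values()) < 1e-9

    def test_displaced_helix_recovered_when_aligned_on_others(self, default_bundle):
        st, tm, _, truth = default_bundle
        moved, _ = perturb_bundle(st, tm, Perturbation(
            displacements={6: 2.2 * outward_unit(6)}), truth)
        others = Selector(chains=["A"], residues=[
            (h.start, h.end) for h in tm.tm_helices() if h.helix_id != 6])
        h6 = tm.helix(6)
        target = Selector(chains=["A"], residues=[(h6.start, h6.end)])
        d = ca_displacements(st, moved, others, target)
        vals = np.array(list(d.values()))
        assert np.all(np.abs(vals - 2.2) < 0.05)


class TestAxesAndTilts:
    def test_vertical_helix_axis_is_z(self):
        # 36 residues = two full 18-residue wheel periods: balanced PCA
        atoms = make_ideal_helix(36, origin=(0, 0, 0), direction=(0, 0, 1))
        coords = np.array([a.position for a in atoms if a.atom_name == "CA"])
        axis, _ = helix_axis(coords)
        assert tilt_angle(axis, [0, 0, 1]) < 1.0
        assert axis[2] > 0  # sign toward increasing residue number

    def test_rotated_axis_recovered(self):
        atoms = make_ideal_helix(36, origin=(0, 0, 0), direction=(0, 0, 1))
        coords = np.array([a.position for a in atoms if a.atom_name == "CA"])
        R = Rotation.from_euler("x", 8, degrees=True)
        axis0, _ = helix_axis(coords)
        axis1, _ = helix_axis(R.apply(coords))
        assert abs(tilt_angle(axis0, axis1) - 8.0) < 0.2

    def test_collinear_points_give_exact_direction(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        axis, _ = helix_axis(line)
        np.testing.assert_allclose(axis, [1.0, 0.0, 0.0], atol=1e-12)

    def test_tilt_angle_conventions(self):
        assert tilt_angle([0, 0, 1], [0, 0, 1]) == 0.0
        assert tilt_angle([0, 0, 1], [0, 0, -1]) == pytest.approx(0.0, abs=1e-6)
        v = [math.sin(math.radians(8)), 0.0, math.cos(math.radians(8))]
        assert tilt_angle([0, 0, 1], v) == pytest.approx(8.0, abs=1e-6)
        assert tilt_angle(v, [0, 0, 1]) == tilt_angle([0, 0, 1], v)

    def test_errors(self):
        with pytest.raises(InputError):
            helix_axis(np.zeros((4, 3)))
        with pytest.raises(InputError):
            tilt_angle([0, 0, 0], [0, 0, 1])

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(hst.lists(hst.floats(-5, 5), min_size=6, max_size=6))
    def test_tilt_symmetric_and_bounded_property(self, values):
        a = np.array(values[:3])
        b = np.array(values[3:])
        assume(np.linalg.norm(a) > 1e-3 and np.linalg.norm(b) > 1e-3)
        t = tilt_angle(a, b)
        assert 0.0 <= t <= 90.0
        assert t == pytest.approx(tilt_angle(b, a), abs=1e-9)
        assert tilt_angle(a, -b) == pytest.approx(t, abs=1e-9)


class TestRotamers:
    def test_dihedral_matches_biopython_on_random_quadruples(self):
        from Bio.PDB.vectors import Vector, calc_dihedral
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.normal(scale=3.0, size=(4, 3))
            ref = math.degrees(calc_dihedral(*(Vector(*q) for q in p)))
            assert dihedral_angle(*p) == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize("chi1,expected", [
        (180.0, "trans"), (-179.0, "trans"), (121.0, "trans"),
        (-65.0, "gauche+"), (-119.0, "gauche+"), (-1.0, "gauche+"),
        (60.0, "gauche-"), (1.0, "gauche-"), (119.0, "gauche-"),
    ])
    def test_constructed_sidechain_classification(self, chi1, expected):
        n = np.array([1.46, 0.0, 0.0])
        ca = np.zeros(3)
        cb = np.array([-0.55, 1.43, 0.0])
        cg = place_atom(n, ca, cb, 1.52, 111.0, chi1)
        atoms = [_atom("N", "N", n, "LEU"), _atom("CA", "C", ca, "LEU"),
                 _atom("CB", "C", cb, "LEU"), _atom("CG", "C", cg, "LEU")]
        res = chi1_rotamer(atoms)
        assert res.chi1 == pytest.approx(chi1, abs=1e-6)
        assert res.chi1_class == expected
        assert classify_chi1(chi1) == expected

    def test_gly_and_ala_undefined(self):
        gly = [_atom("N", "N", [0, 0, 0], "GLY"), _atom("CA", "C", [1.5, 0, 0], "GLY")]
        assert chi1_rotamer(gly).chi1_class == "undefined"
        ala = [_atom(n, e, p, "ALA") for n, e, p in
               [("N", "N", [0, 0, 0]), ("CA", "C", [1.5, 0, 0]), ("CB", "C", [2, 1, 0])]]
        assert chi1_rotamer(ala).chi1_class == "undefined"

    def test_missing_gamma_warns_not_raises(self):
        atoms = [_atom("N", "N", [0, 0, 0], "LEU"), _atom("CA", "C", [1.5, 0, 0], "LEU"),
                 _atom("CB", "C", [2.0, 1.4, 0], "LEU")]
        with pytest.warns(UserWarning):
            res = chi1_rotamer(atoms)
        assert res.chi1_class == "undefined"


class TestContacts:
    def test_far_apart_atoms_no_contacts(self):
        a = Structure([_atom("N", "N", [0, 0, 0])], "a")
        b = Structure([_atom("O", "O", [10, 0, 0])], "b")
        assert detect_contacts(a, b) == []

    def test_constructed_polar_pair(self):
        a = Structure([_atom("N", "N", [0, 0, 0], "ASN")], "a")
        b = Structure([_atom("OD1", "O", [3.0, 0, 0], "ASN", resnum=2)], "b")
        recs = detect_contacts(a, b)
        kinds = {r.kind: r for r in recs}
        assert kinds["polar"].distance == pytest.approx(3.0)
        assert kinds["vdw"].distance == pytest.approx(3.0)

    def test_salt_bridge_and_direction(self):
        arg = Structure([_atom("NH1", "N", [0, 0, 0], "ARG", resnum=1)], "a")
        glu = Structure([_atom("OE1", "O", [3.4, 0, 0], "GLU", resnum=2)], "b")
        recs = [r for r in detect_contacts(arg, glu) if r.kind == "salt_bridge"]
        assert len(recs) == 1
        assert recs[0].atom_a.residue_name == "ARG"
        # symmetric when groups swapped
        recs2 = [r for r in detect_contacts(glu, arg) if r.kind == "salt_bridge"]
        assert len(recs2) == 1 and recs2[0].distance == pytest.approx(recs[0].distance)

    def test_cterminal_carboxylate_accepts_salt_bridge(self):
        lys = Structure([_atom("NZ", "N", [0, 0, 0], "LYS", resnum=1)], "a")
        cterm = Structure([_atom("OXT", "O", [3.2, 0, 0], "TYR", resnum=36),
                           _atom("O", "O", [3.9, 0.6, 0], "TYR", resnum=36)], "b")
        recs = [r for r in detect_contacts(lys, cterm) if r.kind == "salt_bridge"]
        assert len(recs) == 2  # both carboxylate oxygens qualify

    def test_pi_cation_to_ring_centroid(self):
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        ring = []
        for i, nm in enumerate(ring_names):
            ang = math.radians(60 * i)
            ring.append(_atom(nm, "C", [1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0],
                              "PHE", resnum=5))
        phe = Structure(ring, "ring")
        lys = Structure([_atom("NZ", "N", [0, 0, 4.0], "LYS", resnum=9)], "cation")
        recs = [r for r in detect_contacts(lys, phe) if r.kind == "pi_cation"]
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(4.0, abs=1e-9)

    def test_order_permutation_invariant(self, default_bundle):
        st, _, _, _ = default_bundle
        a = Structure(st.atoms[:200], "a")
        b = Structure(st.atoms[200:400], "b")
        rows = {r.as_row() for r in detect_contacts(a, b)}
        rng = np.random.default_rng(3)
        a2 = Structure([a.atoms[i] for i in rng.permutation(len(a.atoms))], "a2")
        b2 = Structure([b.atoms[i] for i in rng.permutation(len(b.atoms))], "b2")
        assert {r.as_row() for r in detect_contacts(a2, b2)} == rows


class TestDistances:
    def test_trivial_values(self):
        a = Structure([_atom("CA", "C", [0, 0, 0])], "a")
        b = Structure([_atom("CA", "C", [3, 4, 0])], "b")
        assert min_distance(a, b) == pytest.approx(5.0)
        assert min_distance(a, a) == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(23)
        xa = rng.uniform(-20, 20, size=(300, 3))
        xb = rng.uniform(-20, 20, size=(300, 3))
        a = Structure([_atom("C1", "C", p, resnum=i) for i, p in enumerate(xa)], "a")
        b = Structure([_atom("C1", "C", p, resnum=i) for i, p in enumerate(xb)], "b")
        brute = min(np.linalg.norm(p - q) for p in xa for q in xb)
        assert min_distance(a, b) == pytest.approx(brute, abs=1e-12)

    def test_hydrogens_ignored(self):
        a = Structure([_atom("CA", "C", [0, 0, 0]), _atom("HA", "H", [0, 0, 0.5])], "a")
        b = Structure([_atom("CA", "C", [4, 0, 0])], "b")
        assert min_distance(a, b) == pytest.approx(4.0)

    def test_empty_group_rejected(self):
        a = Structure([_atom("CA", "C", [0, 0, 0])], "a")
        with pytest.raises(InputError):
            min_distance(a, Structure([], "empty"))

    def test_rigid_transform_invariance(self, default_bundle):
        st, _, _, _ = default_bundle
        a = Structure(st.atoms[:100], "a")
        b = Structure(st.atoms[500:600], "b")
        tf = RigidTransform(Rotation.from_euler("zx", [40, 15], degrees=True).as_matrix(),
                            [5.0, -2.0, 1.0])
        d0 = min_distance(a, b)
        d1 = min_distance(apply_transform(a, tf), apply_transform(b, tf))
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestInsertionDepth:
    def test_constructed_depths(self, default_bundle):
        _, _, _, truth = default_bundle
        bounds = PocketBounds(truth.z_lower, truth.z_upper)
        at_top = Structure([_atom("CA", "C", [0, 0, truth.z_upper])], "p")
        assert insertion_depth(at_top, bounds) == 0.0
        deep = Structure(make_peptide(3, (0, 0, truth.z_upper - 11.0), (0, 0, 1),
                                      spacing=1.0), "pep")
        # lowest heavy atom is the N, 1.2 Å below the first CA
        assert insertion_depth(deep, bounds) == pytest.approx(11.0 + 1.2, abs=1e-9)

    def test_clamped_at_zero_above_surface(self, default_bundle):
        _, _, _, truth = default_bundle
        bounds = PocketBounds(truth.z_lower, truth.z_upper)
        above = Structure([_atom("CA", "C", [0, 0, truth.z_upper + 5.0])], "p")
        assert insertion_depth(above, bounds) == 0.0

    def test_empty_selection_rejected(self, default_bundle):
        _, _, _, truth = default_bundle
        with pytest.raises(InputError):
            insertion_depth(Structure([], "e"),
                            PocketBounds(truth.z_lower, truth.z_upper))


class TestCompareStates:
    def test_identity_pair_reports_no_changes(self, default_bundle):
        st, tm, _, _ = default_bundle
        comp = compare_states(st, st, tm)
        assert max(comp.displacements.values()) < 1e-9
        assert comp.rotamer_changes == {}
        assert all(t < 1e-6 for t in comp.tilts.values())

    def test_tilt_and_rotamer_perturbations_recovered(self, default_bundle):
        st, tm, _, truth = default_bundle
        toggle_resnum = 501 + 22
        moved, truth2 = perturb_bundle(st, tm, Perturbation(
            tilts={3: 8.0}, chi1_set={toggle_resnum: 175.0}), truth)
        # helix-3 axis tilt measured directly (alignment-free)
        h3 = tm.helix(3)
        sel = Selector(chains=["A"], residues=[(h3.start, h3.end)], atom_names=["CA"])
        ax_a, _ = helix_axis(select_atoms(st, sel).coords)
        ax_b, _ = helix_axis(select_atoms(moved, sel).coords)
        assert tilt_angle(ax_a, ax_b) == pytest.approx(8.0, abs=0.2)
        # chi1 change (default-built TRP starts at gauche+)
        comp = compare_states(st, moved, tm)
        key = ("A", toggle_resnum, "")
        assert key in comp.rotamer_changes
        assert comp.rotamer_changes[key][3] == "trans"
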