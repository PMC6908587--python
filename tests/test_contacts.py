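"""Contact detection boundaries and the R/T marker panel."""
import numpy as np
import pytest

from conftest import random_rotation
from hbstate.contacts import (ContactCutoffs, RTMarkerNumbering,
                              ch_pi_contacts, ring_stacking, rt_marker_panel,
                              salt_bridges)
from hbstate.errors import UnitUnavailableError
from hbstate.structure import Chain, Structure
from hbstate.synthetic import HelixSpec, make_ideal_helix, make_residue


def _lys(seq, nz):
    return make_residue("LYS", seq, [("N", [0, 0, 50]), ("CA", [1.5, 0, 50]),
                                     ("CB", [2, 1, 50]), ("NZ", nz)])


def _asp(seq, od1, od2=None):
    atoms = [("N", [20, 0, 50]), ("CA", [21.5, 0, 50]), ("OD1", od1)]
    if od2 is not None:
        atoms.append(("OD2", od2))
    return make_residue("ASP", seq, atoms)


def _ring(name, seq, center, normal, extra=()):
    """Regular planar ring with exact centroid/normal, plus extras."""
    center = np.asarray(center, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(helper @ normal) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    names = {"HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
             "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")}[name]
    r = 1.2
    atoms = []
    for k, atom_name in enumerate(names):
        ang = 2 * np.pi * k / len(names)
        atoms.append((atom_name,
                      center + r * (np.cos(ang) * u + np.sin(ang) * v)))
    atoms += list(extra)
    return make_residue(name, seq, atoms)


def _structure(*residues):
    chain = Chain("A", list(residues))
    chain.sort_residues()
    return Structure("SYN", chains=[chain])


class TestSaltBridges:
    def test_detected_inside_cutoff_absent_outside(self):
        close = _structure(_lys(1, [5, 0, 50]), _asp(10, [5, 3.0, 50]))
        far = _structure(_lys(1, [5, 0, 50]), _asp(10, [5, 4.5, 50]))
        assert len(salt_bridges(close)) == 1
        assert salt_bridges(far) == []
        rec = salt_bridges(close)[0]
        assert rec.geometry["min_distance"] == pytest.approx(3.0)

    def test_boundary_behaviour_at_cutoff(self):
        just_in = _structure(_lys(1, [5, 0, 50]), _asp(10, [5, 3.8, 50]))
        just_out = _structure(_lys(1, [5, 0, 50]), _asp(10, [5, 4.2, 50]))
        assert len(salt_bridges(just_in)) == 1
        assert salt_bridges(just_out) == []

    def test_his_counts_as_basic_partner(self):
        his = make_residue("HIS", 1, [("N", [0, 0, 0]), ("CA", [1.5, 0, 0]),
                                      ("NE2", [5, 0, 50]),
                                      ("ND1", [6, 1, 50])])
        st = _structure(his, _asp(10, [5, 3.0, 50]))
        recs = salt_bridges(st)
        assert len(recs) == 1
        assert recs[0].residue_a[2] == "HIS"

    def test_gly_only_structure_empty(self):
        chain = make_ideal_helix(HelixSpec(8, residue_name="GLY"))
        assert salt_bridges(Structure("G", chains=[chain])) == []

    def test_c_terminal_carboxylate_is_acidic(self):
        helix = make_ideal_helix(HelixSpec(5, residue_name="GLY"))
        last_o = helix.residues[-1].position("O")
        other = Chain("B", [_lys(100, last_o + np.array([0, 0, 2.5]))])
        st = Structure("CT", chains=[helix, other])
        recs = salt_bridges(st)
        assert any(r.residue_b[1] == 5 for r in recs)

    def test_loosening_cutoff_never_removes_records(self):
        st = _structure(_lys(1, [5, 0, 50]), _asp(10, [5, 3.8, 50]),
                        _asp(20, [5, -4.3, 50]))
        tight = {(r.residue_a[:2], r.residue_b[:2])
                 for r in salt_bridges(st, cutoffs=ContactCutoffs(
                     salt_bridge=4.0))}
        loose = {(r.residue_a[:2], r.residue_b[:2])
                 for r in salt_bridges(st, cutoffs=ContactCutoffs(
                     salt_bridge=4.5))}
        assert tight <= loose
        assert len(loose) > len(tight)


class TestChPi:
    def _val(self, seq, cg1):
        return make_residue("VAL", seq, [("N", [10, 10, 0]),
                                         ("CA", [11.5, 10, 0]),
                                         ("CB", [12, 11, 0]), ("CG1", cg1)])

    def test_carbon_above_ring_detected(self):
        st = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                        self._val(10, [0, 0, 3.6]))
        recs = ch_pi_contacts(st)
        assert len(recs) == 1
        assert recs[0].geometry["axial_angle"] == pytest.approx(0.0, abs=1e-6)

    def test_carbon_in_ring_plane_rejected(self):
        st = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                        self._val(10, [3.6, 0, 0]))
        assert ch_pi_contacts(st) == []

    def test_distance_boundary(self):
        just_in = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                             self._val(10, [0, 0, 4.3]))
        just_out = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                              self._val(10, [0, 0, 4.7]))
        assert len(ch_pi_contacts(just_in)) == 1
        assert ch_pi_contacts(just_out) == []


class TestStacking:
    def test_parallel_rings(self):
        st = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                        _ring("PHE", 10, [0, 0, 3.5], [0, 0, 1]))
        recs = ring_stacking(st)
        assert len(recs) == 1
        assert recs[0].geometry["class"] == "parallel"
        assert recs[0].geometry["centroid_distance"] == pytest.approx(3.5)

    def test_perpendicular_rings_t_shaped(self):
        st = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                        _ring("PHE", 10, [0, 0, 5.0], [1, 0, 0]))
        recs = ring_stacking(st)
        assert recs[0].geometry["class"] == "t_shaped"
        assert recs[0].geometry["interplanar_angle"] == pytest.approx(
            90.0, abs=1e-6)

    def test_distance_boundary(self):
        just_out = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                              _ring("PHE", 10, [0, 0, 5.7], [0, 0, 1]))
        assert ring_stacking(just_out) == []

    def test_rigid_motion_invariance(self, rng):
        st = _structure(_ring("HIS", 1, [0, 0, 0], [0, 0, 1]),
                        _ring("PHE", 10, [1.0, 0.5, 4.0], [0.3, 0, 1]),
                        self._extra_val())
        base = [(r.kind, r.residue_a, r.residue_b,
                 round(r.geometry.get("centroid_distance",
                                      r.geometry.get("min_distance")), 6))
                for r in (ring_stacking(st) + ch_pi_contacts(st)
                          + salt_bridges(st))]
        R = random_rotation(rng)
        for _, res in st.iter_residues():
            for a in res.atoms:
                a.position = R @ a.position + np.array([3.0, 1.0, -8.0])
        moved = [(r.kind, r.residue_a, r.residue_b,
                  round(r.geometry.get("centroid_distance",
                                       r.geometry.get("min_distance")), 6))
                 for r in (ring_stacking(st) + ch_pi_contacts(st)
                           + salt_bridges(st))]
        assert base == moved

    @staticmethod
    def _extra_val():
        return make_residue("VAL", 20, [("N", [10, 10, 0]),
                                        ("CA", [11.5, 10, 0]),
                                        ("CG1", [0, 0, -3.4])])


class TestMarkerPanel:
    def _tetramer(self, with_cterm=True, asp_sep=2.5):
        # alpha1: helix C residues 36-42 along a line + Lys40 + Asp95
        a1 = make_ideal_helix(HelixSpec(10, residue_name="GLY"),
                              chain_id="A", start_resnum=30)
        a1.subunit_type = "alpha"
        a1.residues.append(make_residue("ASP", 95, [
            ("N", [0, 20, 0]), ("CA", [1.5, 20, 0]),
            ("OD1", [3.0, 20, 0]), ("OD2", [3.5, 21, 0])]))
        # re-point numbering so Lys40 exists
        a1.residues.append(make_residue("LYS", 40, [
            ("N", [0, 40, 0]), ("CA", [1.5, 40, 0]), ("NZ", [5, 40, 0])]))
        a1.sort_residues()
        b2 = Chain("D", subunit_type="beta")
        b2.residues.append(make_residue("ASP", 101, [
            ("N", [0, 20, 5]), ("CA", [1.5, 20, 5]),
            ("OD1", [3.0, 20, asp_sep]), ("OD2", [4.0, 22, 5])]))
        b2.residues.append(make_residue("ASP", 99, [
            ("N", [0, 24, 5]), ("CA", [1.5, 24, 5]),
            ("OD1", [3.0, 24, 5])]))
        b2.residues.append(make_residue("HIS", 97, [
            ("N", [0, 10, 3]), ("CA", [2.0, 2.3, 3])]))
        if with_cterm:
            b2.residues.append(make_residue("HIS", 146, [
                ("N", [4, 40, 0]), ("CA", [5.5, 40, 0]),
                ("O", [7.0, 40, 0]), ("OXT", [7.5, 41, 0])]))
        b2.sort_residues()
        filler_a2 = make_ideal_helix(HelixSpec(5), chain_id="C")
        filler_a2.subunit_type = "alpha"
        filler_b1 = make_ideal_helix(HelixSpec(5), chain_id="B")
        filler_b1.subunit_type = "beta"
        st = Structure("TOY", chains=[a1, filler_b1, filler_a2, b2])
        return st, {"alpha1": "A", "beta1": "B", "alpha2": "C", "beta2": "D"}

    def test_planted_asp_cluster_distance_recovered(self):
        st, cmap = self._tetramer(asp_sep=2.5)
        panel = rt_marker_panel(st, cmap)
        # OD1(95) at (3,20,0) vs OD1(101) at (3,20,2.5)
        assert panel.asp_cluster_min_oo == pytest.approx(2.5, abs=1e-9)

    def test_c_terminal_salt_bridge_distance(self):
        st, cmap = self._tetramer()
        panel = rt_marker_panel(st, cmap)
        # NZ(Lys40) at (5,40,0), nearest of O(7,40,0)/OXT -> 2.0
        assert panel.lys40_his146_saltbridge == pytest.approx(2.0, abs=1e-9)

    def test_unmodeled_c_terminus_propagates(self):
        st, cmap = self._tetramer(with_cterm=False)
        panel = rt_marker_panel(st, cmap)
        assert panel.lys40_his146_saltbridge == "unmodeled"
        assert any("not assessable" in n for n in panel.verdict_notes)

    def test_his97_offset_from_helix_c_axis(self):
        st, cmap = self._tetramer()
        panel = rt_marker_panel(st, cmap,
                                RTMarkerNumbering(helix_c_range=(30, 39)))
        assert isinstance(panel.his97_c_helix_offset, float)
        assert 0.0 < panel.his97_c_helix_offset < 10.0

    def test_missing_chain_labels_rejected(self, toy_tetramer):
        with pytest.raises(UnitUnavailableError):
            rt_marker_panel(toy_tetramer, {"alpha1": "A"})
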