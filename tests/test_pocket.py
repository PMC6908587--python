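"""Heme detection, His identification and descriptor recovery."""
import numpy as np
import pytest

from conftest import random_rotation
from hbstate.errors import (DegenerateGeometryError, MalformedHemeError,
                            NoProximalHisError)
from hbstate.pocket import (HemeGroup, chi1, descriptor_panel,
                            fe_out_of_plane, find_hemes,
                            identify_distal_his, identify_proximal_his)
from hbstate.structure import Structure
from hbstate.synthetic import (PocketSpec, make_his_residue, make_pocket,
                               make_residue, translate_residue)


def gram_schmidt_dihedral(p0, p1, p2, p3):
    """Independent oracle: dihedral via projection onto the plane normal
    to the central bond, signed by the triple product."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b = p2 - p1
    b = b / np.linalg.norm(b)
    u = (p0 - p1) - ((p0 - p1) @ b) * b
    v = (p3 - p2) - ((p3 - p2) @ b) * b
    cos = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    if np.cross(u, v) @ b < 0:
        ang = -ang
    # the projection convention is the negative of the IUPAC convention
    ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return ang


class TestChi1:
    def test_trans_planar_is_180(self):
        res = make_residue("HIS", 1, [
            ("N", [0, 1, 0]), ("CA", [0, 0, 0]), ("CB", [1.5, 0, 0]),
            ("CG", [1.5, -1, 0])])
        assert chi1(res) == pytest.approx(180.0, abs=1e-9)

    def test_mirror_image_flips_sign(self):
        res = make_his_residue(1, chi1=-77.9)
        assert chi1(res) == pytest.approx(-77.9, abs=1e-9)
        mirrored = res.copy()
        for a in mirrored.atoms:
            a.position = a.position * np.array([1.0, 1.0, -1.0])
        assert chi1(mirrored) == pytest.approx(77.9, abs=1e-9)

    def test_random_conformers_match_gram_schmidt_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3.0
            res = make_residue("HIS", 1, [("N", pts[0]), ("CA", pts[1]),
                                          ("CB", pts[2]), ("CG", pts[3])])
            assert chi1(res) == pytest.approx(
                gram_schmidt_dihedral(*pts), abs=1e-9)


class TestFeOutOfPlane:
    def _heme(self, fe_z, ligand=True):
        half = 2.9 / np.sqrt(2)
        n4 = np.array([[half, 0, 0], [0, half, 0],
                       [-half, 0, 0], [0, -half, 0]])
        lig = [("C", np.array([0, 0, 1.8])), ("O", np.array([0, 0, 2.9]))]
        return HemeGroup(fe=np.array([0.0, 0.0, fe_z]),
                         pyrrole_nitrogens=n4,
                         ligand_atoms=lig if ligand else [])

    def test_iron_in_plane_is_zero(self):
        assert fe_out_of_plane(self._heme(0.0)) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_displacement_toward_ligand_is_positive(self):
        assert fe_out_of_plane(self._heme(0.40)) == pytest.approx(0.40,
                                                                  abs=1e-9)
        assert fe_out_of_plane(self._heme(-0.25)) == pytest.approx(
            -0.25, abs=1e-9)

    def test_collinear_nitrogens_degenerate(self):
        heme = self._heme(0.0)
        heme.pyrrole_nitrogens = np.outer(np.arange(4.0), [1, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            fe_out_of_plane(heme)


class TestHemeDetection:
    def test_synthetic_pocket_heme_found_with_ligand(self, pocket_structure):
        hemes = find_hemes(pocket_structure)
        assert len(hemes) == 1
        assert hemes[0].pyrrole_nitrogens.shape == (4, 3)
        assert hemes[0].ligand_name == "CMO"

    def test_apo_chain_gives_empty_result(self, alpha_helix_chain):
        st = Structure("APO", chains=[alpha_helix_chain.copy()])
        assert find_hemes(st) == []

    def test_heme_without_iron_is_malformed(self, pocket_structure):
        st = pocket_structure.copy()
        hem = st.chain("A").residue(201)
        hem.atoms = [a for a in hem.atoms if a.name != "FE"]
        with pytest.raises(MalformedHemeError):
            find_hemes(st)


class TestHisIdentification:
    def test_proximal_is_coordinating_his(self, pocket_structure):
        heme = find_hemes(pocket_structure)[0]
        chain = pocket_structure.chain("A")
        prox = identify_proximal_his(chain, heme)
        assert prox.seq_number == 87
        ne2 = prox.position("NE2")
        assert np.linalg.norm(ne2 - heme.fe) == pytest.approx(2.1, abs=1e-9)

    def test_nearer_of_two_candidates_wins(self, pocket_structure):
        st = pocket_structure.copy()
        chain = st.chain("A")
        far = translate_residue(make_his_residue(120), [0, 0, -6.0])
        chain.residues.append(far)
        chain.sort_residues()
        heme = find_hemes(st)[0]
        assert identify_proximal_his(chain, heme).seq_number == 87

    def test_no_proximal_raises(self):
        st = make_pocket(PocketSpec(proximal_fe_ne2=5.0))
        heme = find_hemes(st)[0]
        with pytest.raises(NoProximalHisError):
            identify_proximal_his(st.chain("A"), heme)

    def test_distal_by_topology_even_when_displaced(self):
        st = make_pocket(PocketSpec(fe_ne2_distance=11.0,
                                    his_ne2_to_ligand_o=10.3))
        chain = st.chain("A")
        heme = find_hemes(st)[0]
        prox = identify_proximal_his(chain, heme)
        distal = identify_distal_his(chain, heme, prox, e7=59)
        assert distal.seq_number == 59

    def test_distal_geometric_fallback(self, pocket_structure):
        chain = pocket_structure.chain("A")
        heme = find_hemes(pocket_structure)[0]
        prox = identify_proximal_his(chain, heme)
        distal = identify_distal_his(chain, heme, prox, e7=None)
        assert distal.seq_number == 59


class TestDescriptorRecovery:
    @pytest.mark.parametrize("spec", [
        PocketSpec(fe_ne2_distance=2.1, fe_out_of_plane=0.0, chi1=-160.0),
        PocketSpec(fe_ne2_distance=4.4, fe_out_of_plane=0.0, chi1=-77.9),
        PocketSpec(fe_ne2_distance=4.4, fe_out_of_plane=0.3, chi1=60.0),
        PocketSpec(fe_ne2_distance=10.5, fe_out_of_plane=-0.2, chi1=-77.9,
                   his_ne2_to_ligand_o=10.3),
        PocketSpec(fe_ne2_distance=6.5, chi1=175.0, include_ligand=False),
    ])
    def test_descriptors_recover_construction_parameters(self, spec):
        st = make_pocket(spec)
        chain = st.chain("A")
        panel = descriptor_panel(chain, find_hemes(st)[0], e7=59)
        assert panel.fe_ne2_distal == pytest.approx(spec.fe_ne2_distance,
                                                    abs=1e-6)
        assert panel.chi1_distal == pytest.approx(spec.chi1, abs=1e-6)
        assert panel.fe_out_of_plane == pytest.approx(spec.fe_out_of_plane,
                                                      abs=1e-6)
        if spec.his_ne2_to_ligand_o is not None:
            assert panel.his_ne2_to_ligand_o == pytest.approx(
                spec.his_ne2_to_ligand_o, abs=1e-6)
        if not spec.include_ligand:
            assert panel.his_ne2_to_ligand_o is None
            assert "his_ne2_to_ligand_o" in panel.missing

    def test_rigid_motion_invariance(self, rng):
        spec = PocketSpec(fe_ne2_distance=5.0, fe_out_of_plane=0.35,
                          chi1=-77.9)
        st = make_pocket(spec)
        base = descriptor_panel(st.chain("A"), find_hemes(st)[0], e7=59)
        moved = st.copy()
        R = random_rotation(rng)
        t = np.array([7.0, -2.0, 5.0])
        for _, res in moved.iter_residues():
            for a in res.atoms:
                a.position = R @ a.position + t
        panel = descriptor_panel(moved.chain("A"), find_hemes(moved)[0],
                                 e7=59)
        for name in ("fe_ne2_distal", "his_ne2_to_ligand_o",
                     "ca_ca_distal_proximal", "chi1_distal",
                     "fe_out_of_plane"):
            assert getattr(panel, name) == pytest.approx(
                getattr(base, name), abs=1e-9)

    def test_nd1_reported_alongside_ne2(self, pocket_structure):
        panel = descriptor_panel(pocket_structure.chain("A"),
                                 find_hemes(pocket_structure)[0], e7=59)
        assert panel.fe_nd1_distal is not None
        assert panel.fe_nd1_distal != pytest.approx(panel.fe_ne2_distal)
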