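"""Heme-pocket geometry.

Finds heme groups and their exogenous ligand, identifies the proximal (F8,
iron-coordinating) and distal (E7) histidines, and computes the descriptor
panel used to characterise unusual distal-site arrangements:

* Fe - NE2(distal His) distance (also ND1, for transparency);
* NE2(distal His) - ligand oxygen distance (the canonical CO hydrogen-bond
  partner distance; ~3 A in ordinary carbonmonoxy Hbs, >10 A when the
  distal His has left the pocket);
* C-alpha distance between distal and proximal His (overall pocket
  breathing);
* chi1 of the distal His (swung-out side chains show distinctive rotamers);
* signed Fe displacement from the pyrrole-nitrogen plane (hexacoordinate
  states keep the iron in plane; deoxy T states pull it out).

The distal histidine is identified *topologically* (its E7 position from a
per-family configuration map), not by proximity: the interesting cases are
exactly the ones where the E7 His is no longer near the iron.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateGeometryError, MalformedHemeError,
                     MissingAtomError, NoDistalHisError, NoProximalHisError)
from .geometry import dihedral, fit_plane
from .structure import Chain, Residue, Structure

PYRROLE_NITROGENS = ("NA", "NB", "NC", "ND")
HEME_NAMES = {"HEM", "HEC", "HEB"}

#: chi1 is the N-CA-CB-X dihedral; X per residue type.
CHI1_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

#: default E7 (distal His) author numbers for fish/mammal globin chains
DEFAULT_E7 = {"alpha": 59, "beta": 63}


@dataclass
class HemeGroup:
    fe: np.ndarray
    pyrrole_nitrogens: np.ndarray        # (4, 3), NA NB NC ND order
    ligand_atoms: list[tuple[str, np.ndarray]]  # (atom name, position)
    ligand_name: str = ""
    owner_chain_id: str = ""
    heme_seq_number: int = 0

    def ligand_position(self, name: str) -> np.ndarray | None:
        for n, p in self.ligand_atoms:
            if n == name:
                return p
        return None


@dataclass
class PocketDescriptors:
    fe_ne2_distal: float | None
    fe_nd1_distal: float | None
    his_ne2_to_ligand_o: float | None
    ca_ca_distal_proximal: float | None
    chi1_distal: float | None
    fe_out_of_plane: float | None
    distal_his_id: tuple[str, int] | None
    proximal_his_id: tuple[str, int] | None
    missing: list[str] = field(default_factory=list)


def find_hemes(structure: Structure) -> list[HemeGroup]:
    """One HemeGroup per HEM residue; empty list for apo structures.

    The ligand is the nearest non-protein, non-water hetero group with an
    atom within 3.0 A of the iron (CO, O2, CN...); the proximal histidine,
    being protein, never competes.
    """
    hemes = []
    for chain in structure.chains:
        for res in chain.residues:
            if res.name not in HEME_NAMES:
                continue
            fe = res.position("FE")
            if fe is None:
                raise MalformedHemeError(
                    f"{chain.chain_id}/{res.seq_number}: HEM without FE atom")
            npos = [res.position(n) for n in PYRROLE_NITROGENS]
            if any(p is None for p in npos):
                raise MalformedHemeError(
                    f"{chain.chain_id}/{res.seq_number}: HEM missing a "
                    "pyrrole nitrogen")
            npos = np.array(npos)
            d = np.linalg.norm(npos - fe, axis=1)
            if np.any(d <= 1.5) or np.any(d >= 3.0):
                raise MalformedHemeError(
                    f"{chain.chain_id}/{res.seq_number}: Fe-N(pyrrole) "
                    f"distances outside (1.5, 3.0) A: {np.round(d, 2)}")
            ligand_name, ligand_atoms = _find_ligand(structure, fe, res)
            hemes.append(HemeGroup(
                fe=fe, pyrrole_nitrogens=npos, ligand_atoms=ligand_atoms,
                ligand_name=ligand_name, owner_chain_id=chain.chain_id,
                heme_seq_number=res.seq_number))
    return hemes


def _find_ligand(structure: Structure, fe: np.ndarray, heme_res: Residue):
    best = (np.inf, "", [])
    for chain, res in structure.iter_residues():
        if not res.is_hetero or res.is_water or res is heme_res:
            continue
        if res.name in HEME_NAMES:
            continue
        dmin = min(float(np.linalg.norm(a.position - fe)) for a in res.atoms)
        if dmin <= 3.0 and dmin < best[0]:
            best = (dmin, res.name,
                    [(a.name, a.position) for a in res.atoms])
    return best[1], best[2]


def identify_proximal_his(chain: Chain, heme: HemeGroup,
                          max_distance: float = 2.8) -> Residue:
    """The iron-coordinating His: nearest NE2 to Fe within ``max_distance``."""
    best = None
    best_d = np.inf
    for res in chain.standard_residues():
        if res.name != "HIS":
            continue
        ne2 = res.position("NE2")
        if ne2 is None:
            continue
        d = float(np.linalg.norm(ne2 - heme.fe))
        if d < best_d:
            best, best_d = res, d
    if best is None or best_d > max_distance:
        raise NoProximalHisError(
            f"chain {chain.chain_id}: no His NE2 within {max_distance} A "
            "of the heme iron")
    return best


def identify_distal_his(chain: Chain, heme: HemeGroup, proximal: Residue,
                        e7: int | None = None) -> Residue:
    """The E7 distal His, by topology first, geometry as fallback.

    With ``e7`` given (or resolvable from the chain's subunit annotation),
    the residue at that author position is returned regardless of where its
    side chain currently sits. Fallback: the non-proximal His whose NE2
    lies on the ligand side of the heme plane, nearest the iron.
    """
    if e7 is None:
        e7 = DEFAULT_E7.get(chain.subunit_type)
    if e7 is not None:
        res = chain.residue(e7)
        if res is not None and res.name == "HIS":
            return res
    centroid, normal = fit_plane(heme.pyrrole_nitrogens)
    normal = _orient_normal(normal, centroid, heme, proximal)
    best = None
    best_d = np.inf
    for res in chain.standard_residues():
        if res.name != "HIS" or res is proximal:
            continue
        ne2 = res.position("NE2")
        if ne2 is None:
            continue
        if (ne2 - centroid) @ normal <= 0:
            continue
        d = float(np.linalg.norm(ne2 - heme.fe))
        if d < best_d:
            best, best_d = res, d
    if best is None:
        raise NoDistalHisError(
            f"chain {chain.chain_id}: no distal-His candidate (configure "
            "the E7 position)")
    return best


def _orient_normal(normal, centroid, heme: HemeGroup,
                   proximal: Residue | None) -> np.ndarray:
    """Unit normal oriented toward the ligand (distal) side."""
    if heme.ligand_atoms:
        ref = np.mean([p for _, p in heme.ligand_atoms], axis=0)
        sign = np.sign((ref - centroid) @ normal)
    elif proximal is not None and proximal.position("NE2") is not None:
        sign = -np.sign((proximal.position("NE2") - centroid) @ normal)
    else:
        # deterministic fallback: largest-magnitude component positive
        sign = np.sign(normal[np.argmax(np.abs(normal))])
    return normal * (sign if sign != 0 else 1.0)


def chi1(residue: Residue) -> float:
    """First side-chain dihedral N-CA-CB-X in degrees, in (-180, 180]."""
    gamma = CHI1_GAMMA_ATOM.get(residue.name)
    if gamma is None:
        raise MissingAtomError(f"{residue.name} has no chi1")
    atoms = [residue.position(n) for n in ("N", "CA", "CB", gamma)]
    names = ("N", "CA", "CB", gamma)
    for n, p in zip(names, atoms):
        if p is None:
            raise MissingAtomError(
                f"residue {residue.name}{residue.seq_number}: missing {n}")
    return dihedral(*atoms)


def fe_out_of_plane(heme: HemeGroup, proximal: Residue | None = None) -> float:
    """Signed Fe displacement from the pyrrole-N least-squares plane.

    Positive toward the ligand (distal) side. Orthogonal least squares over
    exactly the four pyrrole nitrogens.
    """
    centroid, normal = fit_plane(heme.pyrrole_nitrogens)
    normal = _orient_normal(normal, centroid, heme, proximal)
    return float((heme.fe - centroid) @ normal)


def descriptor_panel(chain: Chain, heme: HemeGroup,
                     e7: int | None = None) -> PocketDescriptors:
    """Full pocket descriptor panel for one chain/heme.

    Individually missing atoms flag the affected field (``missing`` list)
    rather than failing the panel.
    """
    missing: list[str] = []
    proximal = identify_proximal_his(chain, heme)
    distal = identify_distal_his(chain, heme, proximal, e7=e7)

    def dist(p, q):
        return float(np.linalg.norm(p - q))

    ne2 = distal.position("NE2")
    nd1 = distal.position("ND1")
    fe_ne2 = dist(heme.fe, ne2) if ne2 is not None else None
    fe_nd1 = dist(heme.fe, nd1) if nd1 is not None else None
    if ne2 is None:
        missing.append("fe_ne2_distal")

    lig_o = heme.ligand_position("O")
    if lig_o is None and heme.ligand_atoms:
        # CO modelled with a different oxygen name (e.g. O1); take any O
        for n, p in heme.ligand_atoms:
            if n.startswith("O"):
                lig_o = p
                break
    if ne2 is not None and lig_o is not None:
        his_lig = dist(ne2, lig_o)
    else:
        his_lig = None
        missing.append("his_ne2_to_ligand_o")

    ca_d, ca_p = distal.position("CA"), proximal.position("CA")
    if ca_d is not None and ca_p is not None:
        ca_ca = dist(ca_d, ca_p)
    else:
        ca_ca = None
        missing.append("ca_ca_distal_proximal")

    try:
        chi = chi1(distal)
    except MissingAtomError:
        chi = None
        missing.append("chi1_distal")

    try:
        oop = fe_out_of_plane(heme, proximal)
    except DegenerateGeometryError:
        oop = None
        missing.append("fe_out_of_plane")

    return PocketDescriptors(
        fe_ne2_distal=fe_ne2, fe_nd1_distal=fe_nd1,
        his_ne2_to_ligand_o=his_lig, ca_ca_distal_proximal=ca_ca,
        chi1_distal=chi, fe_out_of_plane=oop,
        distal_his_id=(chain.chain_id, distal.seq_number),
        proximal_his_id=(chain.chain_id, proximal.seq_number),
        missing=missing)
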