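"""Coordinate data model and PDB/mmCIF input/output.

The in-memory hierarchy (:class:`Structure` -> :class:`Chain` ->
:class:`Residue` -> :class:`Atom`) is a thin, analysis-oriented view of a
coordinate file. Parsing and fixed-column writing are delegated to gemmi;
the model keeps author residue numbering (the numbering the hemoglobin
literature cites, e.g. His59 of the alpha chain), retains alternate
locations until :func:`resolve_altlocs` is applied, and records any
biological-assembly operators found in the header (REMARK 350 BIOMT or the
mmCIF assembly categories) so an alpha2-beta2 tetramer can be built from a
deposited alpha-beta dimer.
"""
from __future__ import annotations

import copy
import string
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from .errors import (EmptySequenceError, FormatError, InvalidOperatorError,
                     ParseError)
from .geometry import apply_rigid, is_proper_rotation

#: Standard amino acids, three-letter -> one-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Modified residues mapped to their standard parent for sequence purposes.
#: Editable: callers may update this table (e.g. disable the MSE->M mapping).
MODIFIED_PARENT = {"MSE": "M"}

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    """A single atom site (coordinates in Angstrom)."""
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.occupancy, self.altloc, self.b_factor)


@dataclass
class Residue:
    """A residue identified by author numbering."""
    name: str
    seq_number: int
    insertion_code: str = ""
    is_hetero: bool = False
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[int, str]:
        return (self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        """First atom with the given PDB name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def position(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.position

    def has_atoms(self, *names: str) -> bool:
        return all(self.atom(n) is not None for n in names)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_number, self.insertion_code,
                       self.is_hetero, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    #: 'alpha' | 'beta' | 'unknown' globin subunit annotation
    subunit_type: str = "unknown"

    def residue(self, seq_number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_hetero]

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_hetero]

    def sort_residues(self) -> None:
        self.residues.sort(key=lambda r: (r.seq_number, r.insertion_code))

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues],
                     self.subunit_type)


@dataclass
class AssemblyOperator:
    """A rigid operator from the file header, applied to named chains."""
    rotation: np.ndarray
    translation: np.ndarray
    chain_ids: list[str]

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=1e-6)
                and np.allclose(self.translation, 0.0, atol=1e-6))


@dataclass
class Structure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    assembly_transforms: list[AssemblyOperator] = field(default_factory=list)
    source_format: str = "pdb"

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def n_standard_residues(self) -> int:
        return sum(len(c.standard_residues()) for c in self.chains)

    def n_waters(self) -> int:
        return sum(1 for _, r in self.iter_residues() if r.is_water)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for _, r in self.iter_residues()
                         for a in r.atoms])

    def copy(self) -> "Structure":
        return Structure(self.structure_id, [c.copy() for c in self.chains],
                         copy.deepcopy(self.assembly_transforms),
                         self.source_format)

    def transform_chains(self, chain_ids: Iterable[str], rotation,
                         translation, origin=None) -> None:
        """In-place rigid transform of the named chains."""
        ids = set(chain_ids)
        for c in self.chains:
            if c.chain_id not in ids:
                continue
            for r in c.residues:
                for a in r.atoms:
                    a.position = apply_rigid(a.position[None, :], rotation,
                                             translation, origin)[0]


# ---------------------------------------------------------------------------
# parsing

def _infer_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    if ".cif" in suffixes or ".mmcif" in suffixes:
        return "mmcif"
    if ".pdb" in suffixes or ".ent" in suffixes:
        return "pdb"
    return "pdb"


def parse_structure(path, format: str | None = None) -> Structure:
    """Parse a PDB or mmCIF file into the hbstate hierarchy.

    All ATOM/HETATM sites are represented; alternate locations are retained
    (resolve them with :func:`resolve_altlocs`); header assembly operators
    are captured when present. Only the first model of multi-model files is
    read.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format '{fmt}' (expected pdb or mmcif)")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    return _from_gemmi(st, structure_id=path.stem.upper(), source_format=fmt)


def _from_gemmi(st: gemmi.Structure, structure_id: str,
                source_format: str) -> Structure:
    if len(st) == 0:
        raise ParseError(f"{structure_id}: no models in file")
    out = Structure(structure_id=structure_id, source_format=source_format)
    model = st[0]
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        current: Residue | None = None
        for gres in gchain:
            het = gres.het_flag == "H"
            key = (gres.seqid.num, gres.seqid.icode.strip())
            # gemmi splits altloc'd residues; merge sites back per residue id
            if (current is None or current.id != key
                    or (current.name != gres.name and not _altloc_split(gres))):
                current = Residue(name=gres.name, seq_number=key[0],
                                  insertion_code=key[1], is_hetero=het)
                chain.residues.append(current)
            for ga in gres:
                alt = "" if ga.altloc in ("\0", " ", "") else ga.altloc
                current.atoms.append(Atom(
                    name=ga.name, element=ga.element.name.upper(),
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=float(ga.occ), altloc=alt,
                    b_factor=float(ga.b_iso)))
        if chain.residues:
            out.chains.append(chain)
    out.assembly_transforms = _extract_assembly(st, model)
    return out


def _altloc_split(gres) -> bool:
    return any(ga.altloc not in ("\0", " ", "") for ga in gres)


def _extract_assembly(st: gemmi.Structure, model) -> list[AssemblyOperator]:
    ops: list[AssemblyOperator] = []
    if not st.assemblies:
        return ops
    asm = st.assemblies[0]
    for gen in asm.generators:
        chains = list(gen.chains) or [ch.name for ch in model]
        for op in gen.operators:
            tr = op.transform
            ops.append(AssemblyOperator(
                rotation=np.array(tr.mat.tolist()),
                translation=np.array(tr.vec.tolist()),
                chain_ids=chains))
    return ops


# ---------------------------------------------------------------------------
# writing

def to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path) -> None:
    """Write standard fixed-column PDB."""
    to_gemmi(structure).write_pdb(str(path))


def write_mmcif(structure: Structure, path) -> None:
    to_gemmi(structure).make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# operations

def resolve_altlocs(structure: Structure) -> Structure:
    """Keep one atom per (residue, atom name).

    Highest occupancy wins; exact ties are broken by ascending altloc
    letter. Idempotent.
    """
    out = structure.copy()
    for _, res in out.iter_residues():
        best: dict[str, Atom] = {}
        order: list[str] = []
        for atom in res.atoms:
            prev = best.get(atom.name)
            if prev is None:
                best[atom.name] = atom
                order.append(atom.name)
            elif (atom.occupancy, _altloc_rank(atom)) > (
                    prev.occupancy, _altloc_rank(prev)):
                best[atom.name] = atom
        for name in order:
            best[name].altloc = ""
        res.atoms = [best[n] for n in order]
    return out


def _altloc_rank(atom: Atom) -> float:
    # higher rank wins; earlier altloc letters must win ties
    return -ord(atom.altloc) if atom.altloc else 0


def _next_chain_ids(existing: set[str], count: int) -> list[str]:
    pool = string.ascii_uppercase + string.ascii_lowercase + string.digits
    out = []
    for cid in pool:
        if cid not in existing:
            out.append(cid)
            existing.add(cid)
        if len(out) == count:
            return out
    raise ValueError("ran out of single-character chain identifiers")


def _check_operator(rotation) -> None:
    if not is_proper_rotation(np.asarray(rotation, dtype=float), tol=1e-6):
        raise InvalidOperatorError(
            "assembly operator rotation is not proper orthogonal "
            "(det must be +1 within 1e-6)")


def build_assembly(structure: Structure,
                   transforms: Sequence[AssemblyOperator]) -> Structure:
    """Append one transformed copy per (operator, target chain).

    The original chains are untouched; generated chains receive
    deterministic new single-character ids in operator order. The appended
    atom count equals the sum over transforms of the transformed chains'
    atom counts.
    """
    out = structure.copy()
    existing = {c.chain_id for c in out.chains}
    for op in transforms:
        _check_operator(op.rotation)
        targets = [structure.chain(cid) for cid in op.chain_ids]
        missing = [cid for cid, ch in zip(op.chain_ids, targets) if ch is None]
        if missing:
            raise InvalidOperatorError(f"operator targets unknown chains {missing}")
        new_ids = _next_chain_ids(existing, len(targets))
        for new_id, src in zip(new_ids, targets):
            cpy = src.copy()
            cpy.chain_id = new_id
            for r in cpy.residues:
                for a in r.atoms:
                    a.position = op.rotation @ a.position + op.translation
            out.chains.append(cpy)
    return out


def build_biological_assembly(structure: Structure,
                              transforms: Sequence[AssemblyOperator] | None = None
                              ) -> Structure:
    """Apply header (or supplied) assembly operators.

    Standard biological-assembly semantics: an identity operator maps onto
    the already-present chains; every non-identity operator generates new
    chains. A deposited alpha-beta dimer with an identity + two-fold header
    therefore yields the alpha2-beta2 tetramer.
    """
    ops = list(transforms) if transforms is not None else structure.assembly_transforms
    for op in ops:
        _check_operator(op.rotation)
    non_identity = [op for op in ops if not op.is_identity]
    return build_assembly(structure, non_identity)


def extract_sequence(chain: Chain, map_modified: bool = True) -> str:
    """One-letter sequence of the chain's standard residues.

    Hetero residues (heme, waters, ligands) are skipped; modified residues
    with a known parent (e.g. selenomethionine) map to the parent when
    ``map_modified`` is true; anything else unknown maps to X.
    """
    letters = []
    for res in chain.residues:
        if res.name in THREE_TO_ONE:
            letters.append(THREE_TO_ONE[res.name])
        elif res.is_hetero:
            continue
        elif map_modified and res.name in MODIFIED_PARENT:
            letters.append(MODIFIED_PARENT[res.name])
        else:
            letters.append("X")
    if not letters:
        raise EmptySequenceError(
            f"chain {chain.chain_id} has no standard residues")
    return "".join(letters)


def guess_subunit_types(structure: Structure) -> None:
    """Heuristic alpha/beta annotation for globin chains (in place).

    Fish and mammalian Hb alpha chains are 141-143 residues, beta chains
    146-147; chains outside those ranges stay 'unknown'. As a last resort,
    a four-chain structure whose lengths split into two groups of two is
    labelled shorter-pair alpha / longer-pair beta (the universal globin
    pattern). Prefer an explicit configuration map when available.
    """
    for chain in structure.chains:
        n = len(chain.standard_residues())
        if chain.subunit_type != "unknown" or n == 0:
            continue
        if 135 <= n <= 143:
            chain.subunit_type = "alpha"
        elif 144 <= n <= 150:
            chain.subunit_type = "beta"
    protein = [c for c in structure.chains if c.standard_residues()]
    if (len(protein) == 4
            and all(c.subunit_type == "unknown" for c in protein)):
        lengths = sorted({len(c.standard_residues()) for c in protein})
        if len(lengths) == 2:
            short, long_ = lengths
            counts = [len(c.standard_residues()) for c in protein]
            if counts.count(short) == 2 and counts.count(long_) == 2:
                for c in protein:
                    c.subunit_type = ("alpha" if
                                      len(c.standard_residues()) == short
                                      else "beta")


RCSB_URL = "https://files.rcsb.org/download/{accession}.pdb"


def fetch_structure(accession: str, cache_dir) -> Path:
    """Download a PDB entry by 4-character accession (opt-in network use).

    Returns the cached path; an existing cached file is never re-fetched.
    """
    accession = accession.lower()
    if len(accession) != 4:
        raise ValueError(f"not a 4-character accession: {accession!r}")
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{accession}.pdb"
    if target.exists():
        return target
    url = RCSB_URL.format(accession=accession.upper())
    with urllib.request.urlopen(url, timeout=60) as resp:  # pragma: no cover
        target.write_bytes(resp.read())
    return target
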