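"""Residue correspondence, Kabsch superposition and RMSD decomposition.

RMSD values are computed on C-alpha atoms only, following standard practice
for comparing hemoglobin quaternary states: one rigid fit per *unit* (single
chain, alpha1-beta1 dimer, or the full alpha2-beta2 tetramer) over the
pooled C-alpha correspondence of that unit. The contrast between small
per-chain RMSDs and a large tetramer RMSD is what localises a structure
along the R-T quaternary pathway.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .errors import (DegenerateGeometryError, EmptyCorrespondenceError,
                     InsufficientPointsError, UnitUnavailableError)
from .structure import Chain, Structure, extract_sequence

#: (chain_id, seq_number, insertion_code)
ResidueKey = tuple[str, int, str]


@dataclass
class ResidueCorrespondence:
    """Ordered pairing of equivalent residues between two structures."""
    pairs: list[tuple[ResidueKey, ResidueKey]]
    mode: str  # 'by_number' | 'by_alignment'

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def __add__(self, other: "ResidueCorrespondence") -> "ResidueCorrespondence":
        mode = self.mode if self.mode == other.mode else "mixed"
        return ResidueCorrespondence(self.pairs + other.pairs, mode)


@dataclass
class Superposition:
    """Optimal rigid fit x_B ~ R x_A + t and the residual RMSD."""
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# alignment parameters for cross-protein residue pairing
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1.0, -1.0, -5.0, -1.0


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = _MATCH
    al.mismatch_score = _MISMATCH
    al.open_gap_score = _GAP_OPEN
    al.extend_gap_score = _GAP_EXTEND
    return al


def build_correspondence(chain_a: Chain, chain_b: Chain,
                         mode: str = "by_number") -> ResidueCorrespondence:
    """Pair equivalent residues of two chains.

    ``by_number`` pairs identical (seq_number, insertion_code); use it for
    same-protein comparisons where author numbering is consistent.
    ``by_alignment`` pairs via global sequence alignment (match +1,
    mismatch -1, gap open -5, gap extend -1), keeping only aligned non-gap
    columns; use it across species (e.g. the fish-specific insertion at
    position 47 of the alpha chain shifts numbering). Either way a pair is
    kept only when both residues have a C-alpha atom.
    """
    res_a = [r for r in chain_a.standard_residues()]
    res_b = [r for r in chain_b.standard_residues()]
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    if mode == "by_number":
        index_b = {r.id: r for r in res_b}
        for ra in res_a:
            rb = index_b.get(ra.id)
            if rb is None:
                continue
            if ra.atom("CA") is not None and rb.atom("CA") is not None:
                pairs.append(((chain_a.chain_id, *ra.id),
                              (chain_b.chain_id, *rb.id)))
    elif mode == "by_alignment":
        seq_a = extract_sequence(chain_a)
        seq_b = extract_sequence(chain_b)
        aln = _aligner().align(seq_a, seq_b)[0]
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            for ia, ib in zip(range(sa, ea), range(sb, eb)):
                ra, rb = res_a[ia], res_b[ib]
                if ra.atom("CA") is not None and rb.atom("CA") is not None:
                    pairs.append(((chain_a.chain_id, *ra.id),
                                  (chain_b.chain_id, *rb.id)))
    else:
        raise ValueError(f"unknown correspondence mode {mode!r}")
    if not pairs:
        raise EmptyCorrespondenceError(
            f"no residue pairs between chains {chain_a.chain_id} and "
            f"{chain_b.chain_id} ({mode})")
    return ResidueCorrespondence(pairs, mode)


def _check_nondegenerate(coords: np.ndarray, label: str) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError(f"{label} coordinates are collinear")


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of A onto B (Kabsch, SVD form).

    Reflections are excluded: the returned rotation always has det +1.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 point pairs, got {n}")
    _check_nondegenerate(A, "first")
    _check_nondegenerate(B, "second")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    resid = A0 @ R.T - B0
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def ca_coordinates(structure: Structure,
                   keys: Sequence[ResidueKey]) -> np.ndarray:
    coords = []
    for cid, num, icode in keys:
        chain = structure.chain(cid)
        res = chain.residue(num, icode) if chain else None
        ca = res.atom("CA") if res else None
        if ca is None:
            raise EmptyCorrespondenceError(
                f"missing CA for {cid}/{num}{icode}")
        coords.append(ca.position)
    return np.array(coords)


def superpose_correspondence(struct_a: Structure, struct_b: Structure,
                             corr: ResidueCorrespondence) -> Superposition:
    keys_a = [p[0] for p in corr.pairs]
    keys_b = [p[1] for p in corr.pairs]
    return kabsch(ca_coordinates(struct_a, keys_a),
                  ca_coordinates(struct_b, keys_b))


# ---------------------------------------------------------------------------
# unit decomposition

TETRAMER_LABELS = ("alpha1", "beta1", "alpha2", "beta2")


def tetramer_chain_map(structure: Structure) -> dict[str, str]:
    """Map tetramer labels (alpha1, beta1, alpha2, beta2) to chain ids.

    Labels are assigned by assembly order: the first alpha/beta pair is
    dimer 1, the second is dimer 2. Requires subunit_type annotations on
    four chains (two alpha, two beta).
    """
    alphas = [c.chain_id for c in structure.chains if c.subunit_type == "alpha"]
    betas = [c.chain_id for c in structure.chains if c.subunit_type == "beta"]
    if len(alphas) < 2 or len(betas) < 2:
        raise UnitUnavailableError(
            f"{structure.structure_id}: tetramer needs two alpha and two "
            f"beta chains (found {len(alphas)} alpha, {len(betas)} beta); "
            "build the biological assembly and annotate subunit types first")
    return {"alpha1": alphas[0], "beta1": betas[0],
            "alpha2": alphas[1], "beta2": betas[1]}


def _dimer_chain_map(structure: Structure) -> dict[str, str]:
    alphas = [c.chain_id for c in structure.chains if c.subunit_type == "alpha"]
    betas = [c.chain_id for c in structure.chains if c.subunit_type == "beta"]
    if not alphas or not betas:
        raise UnitUnavailableError(
            f"{structure.structure_id}: needs at least one alpha and one "
            "beta chain with subunit_type annotations")
    return {"alpha1": alphas[0], "beta1": betas[0]}


def _unit_labels(unit: str) -> list[str]:
    table = {"alpha_chain": ["alpha1"], "beta_chain": ["beta1"],
             "dimer": ["alpha1", "beta1"], "tetramer": list(TETRAMER_LABELS)}
    if unit not in table:
        raise ValueError(f"unknown unit {unit!r}")
    return table[unit]


def _unit_correspondence(struct_a: Structure, struct_b: Structure,
                         labels: Sequence[str], map_a: dict[str, str],
                         map_b: dict[str, str],
                         mode: str) -> ResidueCorrespondence:
    corr = None
    for label in labels:
        part = build_correspondence(struct_a.chain(map_a[label]),
                                    struct_b.chain(map_b[label]), mode)
        corr = part if corr is None else corr + part
    return corr


def tetramer_correspondence(struct_a: Structure, struct_b: Structure,
                            mode: str = "by_number"
                            ) -> tuple[ResidueCorrespondence,
                                       dict[str, str], dict[str, str]]:
    """Pooled tetramer correspondence with the RMSD-minimising chain pairing.

    Returns (correspondence, label->chain map of A, label->chain map of B).
    """
    map_a = tetramer_chain_map(struct_a)
    map_b0 = tetramer_chain_map(struct_b)
    swap = {"alpha1": "alpha2", "beta1": "beta2",
            "alpha2": "alpha1", "beta2": "beta1"}
    map_b1 = {lab: map_b0[swap[lab]] for lab in TETRAMER_LABELS}
    best = None
    for map_b in (map_b0, map_b1):
        corr = _unit_correspondence(struct_a, struct_b, TETRAMER_LABELS,
                                    map_a, map_b, mode)
        fit = superpose_correspondence(struct_a, struct_b, corr)
        if best is None or fit.rmsd < best[0]:
            best = (fit.rmsd, corr, map_b)
    return best[1], map_a, best[2]


def rmsd_units(struct_a: Structure, struct_b: Structure,
               units: Sequence[str] = ("alpha_chain", "beta_chain",
                                       "dimer", "tetramer"),
               correspondence_mode: str = "by_number") -> pd.DataFrame:
    """C-alpha RMSD per comparison unit between two assembled tetramers.

    When the two deposited tetramers may label their dimers differently,
    both chain assignments that preserve dimer grouping (identity and
    dimer-swap) are tried and the one minimising the tetramer RMSD is used
    for every unit. Returns a table with columns unit, rmsd, n_atoms.
    """
    needs_tetramer = any("2" in lab for u in units for lab in _unit_labels(u))
    try:
        map_a = tetramer_chain_map(struct_a)
        map_b0 = tetramer_chain_map(struct_b)
    except UnitUnavailableError:
        if needs_tetramer:
            raise
        map_a = _dimer_chain_map(struct_a)
        map_b0 = _dimer_chain_map(struct_b)
    if "alpha2" in map_b0:
        swap = {"alpha1": "alpha2", "beta1": "beta2",
                "alpha2": "alpha1", "beta2": "beta1"}
        map_b1 = {lab: map_b0[swap[lab]] for lab in map_b0}
        candidates = []
        for map_b in (map_b0, map_b1):
            corr = _unit_correspondence(struct_a, struct_b, TETRAMER_LABELS,
                                        map_a, map_b, correspondence_mode)
            fit = superpose_correspondence(struct_a, struct_b, corr)
            candidates.append((fit.rmsd, map_b))
        _, map_b = min(candidates, key=lambda c: c[0])
    else:
        map_b = map_b0

    rows = []
    for unit in units:
        labels = _unit_labels(unit)
        corr = _unit_correspondence(struct_a, struct_b, labels,
                                    map_a, map_b, correspondence_mode)
        fit = superpose_correspondence(struct_a, struct_b, corr)
        rows.append({"unit": unit, "rmsd": fit.rmsd, "n_atoms": fit.n_atoms})
    return pd.DataFrame(rows)
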