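"""Hydrogen-bond-based secondary-structure assignment (Kabsch-Sander style).

Globin chains are all-alpha, so this module detects exactly what the
R-T comparison needs: alpha helices (H, i -> i+4 backbone hydrogen bonds)
and 3-10 helices (G, i -> i+3), with isolated turns reported as T and
everything else as '-'. Beta-ladder logic is deliberately omitted (see the
methods note); a full eight-state assigner would be untested surface here.

The hydrogen-bond energy is the classic electrostatic model

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond called when E < -0.5 kcal/mol, evaluated with an amide
hydrogen reconstructed from the preceding peptide unit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ClashError
from .structure import Chain, Residue

HB_COUPLING = 27.888  # kcal/mol * A, q1*q2*f of the Kabsch-Sander model
HB_CUTOFF = -0.5      # kcal/mol; bond flagged below this energy
HB_CLAMP = -9.9       # kcal/mol; closest-approach clamp
CHAIN_BREAK_CA = 4.5  # A; larger CA(i)-CA(i+1) gaps terminate turn patterns


@dataclass
class BackboneResidue:
    """A residue with complete backbone, plus the virtual amide H."""
    residue: Residue
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None = None  # None for prolines and chain starts


@dataclass
class SecStructAssignment:
    """Per-residue code in {H, G, T, -} over complete-backbone residues."""
    codes: str
    residue_ids: list[tuple[int, str]]
    chain_id: str = ""
    structure_id: str = ""

    def __post_init__(self):
        if len(self.codes) != len(self.residue_ids):
            raise ValueError("codes and residue ids differ in length")


def backbone_trace(chain: Chain) -> list[BackboneResidue]:
    """Standard residues with complete N, CA, C, O backbone, in order."""
    out = []
    for res in chain.standard_residues():
        if res.has_atoms("N", "CA", "C", "O"):
            out.append(BackboneResidue(res, res.position("N"),
                                       res.position("CA"), res.position("C"),
                                       res.position("O")))
    return out


def _breaks(trace: list[BackboneResidue]) -> list[bool]:
    """breaks[i] is True when a chain break lies between i and i+1."""
    flags = []
    for a, b in zip(trace, trace[1:]):
        flags.append(bool(np.linalg.norm(b.ca - a.ca) > CHAIN_BREAK_CA))
    return flags


def place_amide_hydrogens(trace: list[BackboneResidue]) -> None:
    """Reconstruct each amide H (in place) from the previous peptide unit.

    H sits 1.0 A from N along the unit vector C(i-1) -> O(i-1) reversed,
    i.e. ``H = N + unit(C_prev - O_prev)`` — the DSSP convention. The first
    residue, residues after a chain break, and prolines get no H.
    """
    breaks = _breaks(trace)
    for i, br in enumerate(trace):
        br.h = None
        if i == 0 or br.residue.name == "PRO" or breaks[i - 1]:
            continue
        prev = trace[i - 1]
        d = prev.c - prev.o
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            continue
        br.h = br.n + d / nd


def hbond_energy(donor: BackboneResidue, acceptor: BackboneResidue) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol).

    ``donor`` supplies N-H, ``acceptor`` supplies C=O. Returns 0 when the
    donor has no amide hydrogen.
    """
    if donor.h is None:
        return 0.0
    r_on = float(np.linalg.norm(acceptor.o - donor.n))
    r_ch = float(np.linalg.norm(acceptor.c - donor.h))
    r_oh = float(np.linalg.norm(acceptor.o - donor.h))
    r_cn = float(np.linalg.norm(acceptor.c - donor.n))
    dists = (r_on, r_ch, r_oh, r_cn)
    if min(dists) < 0.5:
        raise ClashError(
            f"atoms {min(dists):.2f} A apart between residues "
            f"{donor.residue.seq_number} and {acceptor.residue.seq_number}")
    e = HB_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, HB_CLAMP)


def _turn_flags(trace: list[BackboneResidue], n: int) -> list[bool]:
    """turn[i] is True when CO(i) accepts an H-bond from NH(i+n)."""
    breaks = _breaks(trace)
    flags = [False] * len(trace)
    for i in range(len(trace) - n):
        if any(breaks[i:i + n]):
            continue
        if hbond_energy(trace[i + n], trace[i]) < HB_CUTOFF:
            flags[i] = True
    return flags


def assign_secondary_structure(chain: Chain, structure_id: str = ""
                               ) -> SecStructAssignment:
    """Assign H / G / T / '-' codes over the chain's backbone residues.

    An n-turn at i means an H-bond CO(i) -> NH(i+n); two consecutive
    4-turns start an H stretch (residues i..i+3), two consecutive 3-turns a
    G stretch (i..i+2), with H taking precedence on overlap; residues
    covered only by isolated turns are T. Chains shorter than five
    backbone-complete residues come back all '-'.
    """
    trace = backbone_trace(chain)
    place_amide_hydrogens(trace)
    m = len(trace)
    codes = ["-"] * m
    if m >= 5:
        turn3 = _turn_flags(trace, 3)
        turn4 = _turn_flags(trace, 4)
        is_h = [False] * m
        is_g = [False] * m
        for i in range(1, m):
            if turn4[i - 1] and turn4[i]:
                for j in range(i, min(i + 4, m)):
                    is_h[j] = True
        for i in range(1, m):
            if turn3[i - 1] and turn3[i]:
                for j in range(i, min(i + 3, m)):
                    is_g[j] = True
        in_turn = [False] * m
        for n, flags in ((3, turn3), (4, turn4)):
            for i, f in enumerate(flags):
                if f:
                    for j in range(i + 1, min(i + n, m)):
                        in_turn[j] = True
        for i in range(m):
            if is_h[i]:
                codes[i] = "H"
            elif is_g[i]:
                codes[i] = "G"
            elif in_turn[i]:
                codes[i] = "T"
    return SecStructAssignment(
        codes="".join(codes),
        residue_ids=[br.residue.id for br in trace],
        chain_id=chain.chain_id, structure_id=structure_id)


def helix_segments(assignment: SecStructAssignment
                   ) -> list[tuple[int, int, str]]:
    """Maximal H and G runs as (start_resnum, end_resnum, type)."""
    segments = []
    start = None
    current = "-"
    codes = assignment.codes
    nums = [rid[0] for rid in assignment.residue_ids]
    for i, code in enumerate(codes + "-"):
        code = code if code in ("H", "G") else "-"
        if code != current:
            if current in ("H", "G"):
                segments.append((nums[start], nums[i - 1], current))
            start = i if code in ("H", "G") else None
            current = code
    return segments


def segment_overlapping(segments, res_range: tuple[int, int],
                        kind: str | None = None) -> bool:
    """True when any (start, end, type) segment overlaps ``res_range``."""
    lo, hi = res_range
    for start, end, t in segments:
        if kind is not None and t != kind:
            continue
        if start <= hi and end >= lo:
            return True
    return False


def comparison_track(assign_a: SecStructAssignment,
                     assign_b: SecStructAssignment) -> str:
    """Two-track text comparing assignments by residue number."""
    ids = sorted(set(assign_a.residue_ids) | set(assign_b.residue_ids))
    map_a = dict(zip(assign_a.residue_ids, assign_a.codes))
    map_b = dict(zip(assign_b.residue_ids, assign_b.codes))
    header = "".join(str(num)[-1] for num, _ in ids)
    track_a = "".join(map_a.get(rid, " ") for rid in ids)
    track_b = "".join(map_b.get(rid, " ") for rid in ids)
    return "\n".join([header, track_a, track_b])
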