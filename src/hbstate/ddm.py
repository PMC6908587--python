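"""Intra-structure C-alpha distance matrices and difference distance
matrices (DDMs).

A DDM is the elementwise difference of two structures' internal C-alpha
distance matrices over a shared residue correspondence. Because it uses
only internal distances it is completely superposition-free, which makes it
the standard tool for asking *where* two tetramers differ: a rigidly moved
dimer leaves its intra-dimer blocks at zero while the inter-dimer blocks
light up.

Sign convention: ``delta = d(first argument) - d(second argument)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import EmptyCorrespondenceError
from .structure import Structure
from .superpose import ResidueCorrespondence, ResidueKey, ca_coordinates


@dataclass
class DistanceMatrix:
    labels: list[ResidueKey]
    values: np.ndarray
    structure_id: str = ""


@dataclass
class DifferenceDistanceMatrix:
    labels: list[ResidueKey]          # labels on the first structure's side
    delta: np.ndarray                 # d_A - d_B, Angstrom
    structure_id_a: str = ""
    structure_id_b: str = ""
    chain_labels: dict[str, str] | None = None  # chain_id -> display label

    def block_slice(self, chain_i: str, chain_j: str):
        idx_i = [k for k, lab in enumerate(self.labels) if lab[0] == chain_i]
        idx_j = [k for k, lab in enumerate(self.labels) if lab[0] == chain_j]
        return np.ix_(idx_i, idx_j)


def distance_matrix(structure: Structure,
                    labels: list[ResidueKey] | None = None) -> DistanceMatrix:
    """Symmetric C-alpha distance matrix over ``labels``.

    Defaults to every standard residue with a C-alpha (residues lacking one
    are silently dropped).
    """
    if labels is None:
        labels = [(c.chain_id, r.seq_number, r.insertion_code)
                  for c in structure.chains for r in c.standard_residues()
                  if r.atom("CA") is not None]
    coords = ca_coordinates(structure, labels)
    values = squareform(pdist(coords))
    return DistanceMatrix(labels=list(labels), values=values,
                          structure_id=structure.structure_id)


def difference_matrix(struct_a: Structure, struct_b: Structure,
                      correspondence: ResidueCorrespondence,
                      chain_labels: dict[str, str] | None = None
                      ) -> DifferenceDistanceMatrix:
    """DDM restricted to corresponding residues: D_A - D_B."""
    if correspondence.n_pairs == 0:
        raise EmptyCorrespondenceError("empty correspondence for DDM")
    keys_a = [p[0] for p in correspondence.pairs]
    keys_b = [p[1] for p in correspondence.pairs]
    da = squareform(pdist(ca_coordinates(struct_a, keys_a)))
    db = squareform(pdist(ca_coordinates(struct_b, keys_b)))
    return DifferenceDistanceMatrix(
        labels=keys_a, delta=da - db,
        structure_id_a=struct_a.structure_id,
        structure_id_b=struct_b.structure_id,
        chain_labels=chain_labels)


def block_summary(ddm: DifferenceDistanceMatrix) -> pd.DataFrame:
    """Mean and max |delta-d| per unordered chain pair.

    One row per chain-pair block (alpha1/alpha2, alpha1/beta2, ...); the
    diagonal of same-chain blocks is excluded from the means.
    """
    chains = []
    for lab in ddm.labels:
        if lab[0] not in chains:
            chains.append(lab[0])
    rows = []
    for ci, cj in combinations_with_replacement(chains, 2):
        block = np.abs(ddm.delta[ddm.block_slice(ci, cj)])
        if ci == cj:
            n = block.shape[0]
            vals = block[~np.eye(n, dtype=bool)] if n > 1 else np.array([0.0])
        else:
            vals = block.ravel()
        name = ddm.chain_labels or {}
        rows.append({
            "chain_i": name.get(ci, ci), "chain_j": name.get(cj, cj),
            "mean_abs": float(vals.mean()) if vals.size else 0.0,
            "max_abs": float(vals.max()) if vals.size else 0.0,
        })
    return pd.DataFrame(rows)


def render_ddm(ddm: DifferenceDistanceMatrix, clamp: tuple[float, float] = (-2.0, 2.0),
               out_path=None, csv_path=None) -> np.ndarray:
    """Render the DDM with a diverging colormap clamped to ``clamp``.

    Negative values render red, positive blue (matching the convention of
    plotting d_A - d_B with A the more compact state on red). The returned
    array is the clamped matrix actually plotted; ``csv_path`` receives the
    unclamped matrix.
    """
    lo, hi = clamp
    if not lo < hi:
        raise ValueError("clamp range must be increasing")
    clamped = np.clip(ddm.delta, lo, hi)
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5.5))
        im = ax.imshow(clamped, cmap="RdBu", vmin=lo, vmax=hi, origin="lower")
        ax.set_title(f"DDM: {ddm.structure_id_a} - {ddm.structure_id_b}")
        ax.set_xlabel("residue index")
        ax.set_ylabel("residue index")
        # chain-boundary guides
        bounds = []
        for k in range(1, len(ddm.labels)):
            if ddm.labels[k][0] != ddm.labels[k - 1][0]:
                bounds.append(k - 0.5)
        for b in bounds:
            ax.axhline(b, color="k", lw=0.5)
            ax.axvline(b, color="k", lw=0.5)
        fig.colorbar(im, ax=ax, label=r"$\Delta d$ ($\AA$)")
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    if csv_path is not None:
        header = ",".join(f"{c}:{n}{i}" for c, n, i in ddm.labels)
        np.savetxt(csv_path, ddm.delta, delimiter=",", header=header,
                   comments="# ")
    return clamped


def read_ddm_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", comments="#")
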