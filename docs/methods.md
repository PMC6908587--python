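# Methods

## Scope and model

`hbstate` treats a hemoglobin structure as a hierarchy of chains, residues
and atoms in Å, using **author residue numbering** throughout, because that
is the numbering the hemoglobin literature uses for its landmarks (His59 of
the α chain, His63/His97/His146 of the β chain, the E7/F8 topological
positions). Parsing and fixed-column writing go through gemmi (PDB and
mmCIF, first model only); alternate locations are kept on input and
resolved on demand — highest occupancy wins, exact ties go to the
alphabetically first altloc, a deterministic and standard rule. Hydrogens
are ignored on input; the only hydrogen the analysis needs (the backbone
amide H) is reconstructed geometrically.

Biological assemblies come from explicit header operators (REMARK 350
BIOMT or the mmCIF assembly categories) or user-supplied operators; there
is deliberately no crystallographic-symmetry engine, so nothing is ever
guessed from a space-group symbol. Two operator semantics exist because
both are useful: `build_assembly` appends one copy per operator × chain
(explicit construction), while `build_biological_assembly` follows the
standard convention in which an identity operator designates the chains
already present — a deposited αβ dimer with an identity + two-fold header
becomes the α₂β₂ tetramer with four chains.

α/β subunit identity is taken from an explicit configuration wherever
possible. The fallback heuristic uses chain length (globin α chains are
141–143 residues, β chains 146–147, across fish and mammals), with a last
resort for four-chain structures whose lengths split 2+2 (shorter pair α).
Chain identifiers alone are never trusted.

## Superposition and RMSD decomposition

Superposition is the closed-form Kabsch solution via SVD of the 3×3
covariance of centered Cα coordinates, with the reflection branch excluded
(determinant forced to +1). Inputs with fewer than three pairs or with a
collinear point set are rejected rather than silently fitted. The
independent check in the test suite is the quaternion key-matrix
eigenvalue method, which obtains the optimal score without constructing a
rotation; the two agree to 1e-9 Å on random instances.

Residue correspondence is by identical author number within one protein,
and by global sequence alignment across proteins (match +1, mismatch −1,
gap open −5, gap extend −1; only aligned non-gap columns with Cα on both
sides are kept). The alignment route matters across fish species because
of the fish-specific insertion near position 47 of the α chain. Residues
unmodeled in either structure simply drop out of the correspondence; no
imputation.

The RMSD decomposition performs **one rigid fit per unit** over the pooled
Cα correspondence of that unit: α chain, β chain, α₁β₁ dimer, α₂β₂
tetramer. When two tetramers could pair their dimers either way, both
dimer-preserving assignments are tried and the one minimising the tetramer
RMSD is used for every unit. The toy-tetramer generator's default
dimer1→dimer2 transform is intentionally *not* an involution so that this
assignment is well defined on synthetic ground truth.

## Difference distance matrices

The DDM is Δd = D_A − D_B over the shared correspondence, where D is the
internal Cα–Cα distance matrix — superposition-free by construction, which
the suite verifies to 1e-9 under random rigid motions of either input.
Sign convention: first argument minus second; rendering clamps to ±2 Å on
a diverging red–blue map (negative red). Block summaries report mean and
max |Δd| per unordered chain pair, excluding the diagonal of same-chain
blocks; chains are labelled α1/β1/α2/β2 by assembly order. The block table
is this package's quantification of what is usually judged visually from
DDM images; it is an operational choice, not a community standard.

## Secondary structure

Assignment is hydrogen-bond based in the Kabsch–Sander style. The amide H
sits 1.0 Å from N opposite the preceding carbonyl (H = N + unit(C_prev −
O_prev)); prolines, chain starts and residues after a chain break
(Cα–Cα > 4.5 Å) get none. The bond energy is the classic electrostatic
model E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, clamped at
−9.9, with a bond below −0.5. An n-turn at i is a CO(i)→NH(i+n) bond;
two consecutive 4-turns open an H (α) stretch, two consecutive 3-turns a
G (3₁₀) stretch, H taking precedence on overlap — the precedence rule is
what decides whether a short 3₁₀ insert next to an α helix is reported as
G. Isolated turns are T; everything else is "-".

Deliberate omissions: no β-ladder (E) logic — globins are all-α, and any
sheet machinery here would be untested surface; residues a full
eight-state assigner would call E come back "-". π-helices are folded into
H. Helix boundaries are compared by **segment overlap**, not exact
termini, because independent implementations legitimately disagree by a
residue at helix ends; the suite requires ≥ 95 % per-residue agreement
with an independent full DSSP implementation (mdtraj's) on ideal-helix
fixtures.

## Heme pocket

A heme is a HEM residue with its FE and four pyrrole nitrogens (Fe–N
distances sanity-checked against (1.5, 3.0) Å); the exogenous ligand is
the nearest non-water hetero group with an atom within 3.0 Å of the iron.
The proximal (F8) His is the one whose Nε2 coordinates the iron (nearest,
≤ 2.8 Å). The distal His is identified **topologically** from a configured
E7 author position (defaults 59 for α, 63 for β chains of fish Hbs), with
a geometric fallback (nearest non-proximal His on the ligand side of the
heme plane). Topology first is essential: the scientifically interesting
pockets are exactly those where the E7 His has moved away, and a
proximity rule would silently measure the wrong residue there.

Descriptors: Fe–Nε2 and Fe–Nδ1 of the distal His (both reported; Nε2 is
the canonical hydrogen-bonding atom in carbonmonoxy hemoglobins),
Nε2–O(ligand) using the CO oxygen, distal–proximal Cα–Cα, χ1
(N–CA–CB–CG, atan2 formulation, range (−180°, 180°], cross-checked in the
suite against a projection-based second implementation), and the signed
Fe displacement from the orthogonal-least-squares plane of exactly the
four pyrrole nitrogens (positive toward the ligand side). The four-atom
plane rather than the full 24-atom porphyrin is smaller, standard and
sufficient for the in-plane/out-of-plane call. Note that the sign of the
out-of-plane displacement is defined relative to the ligand side, a
convention that is invariant under reflection (unlike χ1, which flips);
missing atoms flag individual fields instead of failing the panel.

## Contacts and R/T markers

Interaction detection is purely geometric — no energies, no protonation
(His counts as a potential salt-bridge base at any pH, noted in output).
Cutoffs are common structural-biology practice and all config-exposed:
salt bridge 4.0 Å (basic N to acidic O, including C-terminal O/OXT),
CH–π 4.5 Å and 40° off the ring normal, stacking 5.5 Å centroid–centroid
with parallel ≤ 30°, T-shaped ≥ 60°. Detection is monotone in every
cutoff (loosening never removes a record), verified by boundary tests at
cutoff ± 0.2 Å.

The R/T marker panel reports raw geometry without verdict thresholds: the
minimum carboxyl O–O separation of the Asp95α1/Asp101β2 pair (plus each
to Asp99β2), the Lys40α1 Nζ to His146β2 C-terminal carboxylate distance
(a T-state fingerprint), and the distance of Cα(His97β2) from the
orthogonal-least-squares axis through the α1 helix-C Cα range (default
residues 36–42, configurable). Anything absent from the model propagates
as the string `unmodeled` — a disordered β C-terminus must surface as
"not assessable", never as a fabricated distance.

## Survey

The batch survey takes a frozen, user-provided file list (structure
selection — e.g. a sequence search of the PDB — is out of scope precisely
because it is database-version dependent) and records one row per chain
with a heme. Coordination classes operationalise the populations seen in
Fe–Nε2 distance distributions: bis-histidyl ≤ 3.0 Å, canonical distal
(3.0, 6.0] Å, displaced > 6.0 Å, unclassified when unmeasurable; both
boundaries are config-exposed, and classification is a total monotone step
function (boundary-tested at exactly 3.0 and 6.0). Failures on individual
files are logged and never abort the batch; output order is
(structure, chain) regardless of input order. Histograms use a fixed bin
origin at 0 Å.

## Synthetic ground truth

The generator exists so that every stage has a no-download oracle:

* **Ideal helices** are grown by natural-extension (NeRF) placement from
  ideal peptide internal coordinates (N–CA 1.458, CA–C 1.525, C–N 1.329,
  C–O 1.231 Å; angles 111.0/116.6/121.7°) and canonical dihedrals —
  α: φ/ψ = −57.8/−47.0°, 3₁₀: −49.0/−26.0°, extended: −140/135°. Building
  from dihedrals (rather than placing backbone atoms around a Cα cylinder)
  was a deliberate choice: backbone hydrogen-bond geometry then emerges
  correctly by construction, and the resulting Cα spiral reproduces the
  textbook parameters anyway (rise 1.54 Å, twist 99.3°, radius 2.28 Å,
  consecutive Cα–Cα 3.81 Å for the α type). The carbonyl O is placed on
  the bisector of the C→N(next) and C→CA directions.
* **Heme pockets** realise a descriptor specification exactly: pyrrole N₄
  square of side 2.9 Å (Fe–N ≈ 2.05 Å) in z = 0, iron displaced by the
  requested out-of-plane value along +z, CO up the z axis (Fe–C 1.80,
  C–O 1.13 Å), His stubs (backbone + CB/CG/ND1/CD2/CE1/NE2) built with an
  exact χ1 and rigid-placed so Nε2 satisfies the requested Fe–Nε2 and,
  when constrained, Nε2–O(ligand) distances simultaneously (the
  two-sphere intersection; an impossible pair raises an infeasible-spec
  error). Descriptor recovery is exact to 1e-6 and is the core
  parameter-recovery test surface.
* **Toy tetramers** are two rigid-body copies of an αβ-like dimer of ideal
  helices (α 24 residues, β 28, so the subunits are distinguishable). The
  default dimer transform (150° about z plus a translation) is not an
  involution, making chain pairing unambiguous. Controlled perturbations
  (`perturb_rigid`) move exactly the named chains about their centroid by
  default; optional Gaussian jitter is the only source of randomness and
  is always seeded.

What the synthetic data deliberately does **not** emulate: real side-chain
packing, crystallographic disorder, alternate conformations in context,
solvent, or realistic inter-subunit interfaces. Passing the property suite
therefore demonstrates correctness of the geometry and of the decision
rules, not robustness to the full messiness of experimental models; the
deposited-structure acceptance tests cover the latter and require the
(non-redistributable) coordinate files cached locally.

## Numerical choices

Degenerate inputs raise typed errors rather than returning garbage:
< 3 points or collinear sets for superposition, collinear nitrogens for
plane fits, zero-length rotation axes. Collinearity is judged by the
second singular value relative to the first (1e-8). Dihedrals use the
atan2 form (stable near planarity) with −180° folded onto +180°. The
interplanar angle of two rings folds the arbitrary normal orientation into
[0°, 90°]. Rigid-motion invariance of every analysis is asserted at 1e-9.
Report JSON is written with sorted keys so byte-identical reruns are
testable on one platform; cross-platform agreement is expected to 1e-9,
not to the byte.

## Problem sizes in the default runs

The shipped test suite and the acceptance script use 30-residue helices,
single-pocket chains, 24/28-residue toy tetramers (104 pooled Cα per
tetramer comparison), 100 random instances for the oracle-agreement check
and an 8-structure synthetic survey — sizes chosen so every property is
exercised end-to-end (parse → analyse → report, including PDB round
trips) while the whole suite stays interactive-fast.
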