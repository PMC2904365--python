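# Methods

## Scope and model

`groovedock` models the selection of a TCR-Vβ/peptide/MHC-class-II ternary
complex as a rigid-body problem: given a receptor (peptide-MHC surface) and a
probe (TCR variable domain), enumerate rigid placements of the probe, score
their shape complementarity on a grid, remove electrostatically repulsive and
biologically implausible placements, and select the survivor with the best
interface. No conformational flexibility, minimization, or solvent model is
included; survivors are rescored rigidly.

## Grid docking

The static molecule is digitized onto an N³ lattice (default 64³ at 1.0
Å/cell): a cell is occupied iff its center lies within an atom's radius.
Occupied cells within `surface_thickness` of an unoccupied cell form the
surface layer (value 1); the rest are core (value ρ < 0). The mobile molecule
contributes 1 in every occupied cell. The correlation over all cyclic
translations is computed per rotation with forward/inverse FFTs and rounded
to integers; rotations come from a de-duplicated z-y-z Euler sweep
(default 15°, 6384 distinct rotations) with the identity first, so
tie-breaking (score, then rotation index, then lexicographic translation) is
deterministic. Grids are zero-padded so the mobile structure never wraps.

Three numerical choices matter and are config-exposed (`DockParams`):

* `contact_inflation` (default 1.2 Å). Occupancy shells built from
  united-atom radii (C 1.87, N 1.65, O 1.40 Å) only intersect when atoms
  approach closer than ~3.3 Å, which the Lennard-Jones model forbids; a
  docking grid built from bare radii therefore scores a van-der-Waals kiss as
  zero contact. During docking the *static* occupancy radii are inflated by
  this margin, so surfaces in contact (3.3-4.2 Å atom pairs) share cells.
* `surface_thickness` (default 2.0 Å). The surface layer must be at least as
  deep as the inflation margin plus digitization slop, otherwise genuine
  contacts land in core cells and are annihilated by ρ.
* `core_penalty` ρ (default −30). Strong enough that pressing one cell past
  the contact envelope costs more than the extra overlap gains; with the two
  defaults above, the score optimum of the reference benchmark sits at the
  native cell rather than one cell deeper.

These defaults were calibrated once on the synthetic benchmark so that the
score landscape's optimum coincides with van-der-Waals contact; they are the
package's own choices for internals the original FFT-docking programs do not
publish, and all three are ordinary parameters a user can change.

`dock()` computes FFTs in float32 (measured error < 0.01 on benchmark-sized
grids, far below the 0.5 integer-rounding margin); the public `correlate()`
operation uses float64 and is integer-exact against direct summation.

## Electrostatic screen

Per pose, E = Σ 332.0637·q_i·q_j / (f·r²) kcal/mol over charged atom pairs,
with a distance-dependent dielectric ε(r) = f·r (default f = 4). Poses with
E > 0 are removed. Charges are simplified formal charges: −0.5 on each
carboxylate oxygen of Asp/Glu, +1 on Lys NZ, +0.5 on each Arg NH; all other
atoms neutral.

## Filters

Constraint tokens follow the compact notation `R C:T` / `(R1-R2)C:T`
(hyphen, en-dash and minus accepted in ranges). A pose survives iff for every
constraint the minimum any-atom distance between the probe residue and the
target chain is strictly below the cutoff (default 4.5 Å); hydrogens are
included unless `heavy_only` is set. A constraint that names a missing chain
or residue raises, never silently passes. Staged mode applies
receptor-facing constraints before peptide-facing ones and reports per-stage
survivor counts; the final set equals single-stage filtering.

The register filter operationalizes "the CDR3 loop must focus on the central
peptide positions" as a nearest-residue rule: the peptide residue with the
minimum heavy-atom distance to the centroid of the designated loop residues
must carry an allowed register label. The register map (residue number →
P-label) is always caller-supplied, never inferred from the sequence.

## Interface analysis

* **ASA**: golden-spiral quasi-uniform sampling (default 960 points/atom;
  seed-free, bit-reproducible). Each atom's accessible area is
  4π(r+probe)² times the fraction of points outside every neighbor's
  expanded sphere (probe 1.4 Å). Interface ASA is the total buried area,
  both sides: ASA(A) + ASA(B) − ASA(A∪B). Isolated-atom error < 0.5% and
  two-sphere closed-form error < 1% at the defaults; self-convergence
  (4000 vs 16000 points) is within 1%.
* **Interaction energy**: 6-12 Lennard-Jones with ε_ij = √(ε_i·ε_j),
  Rmin_ij = rmin_half_i + rmin_half_j, plus the Coulomb term above, over
  inter-part pairs within 12 Å. The parameter set is the compact per-element
  table shipped with the package; absolute energies are therefore comparable
  only between structures scored by this package, not to any external force
  field. The 12 Å cutoff keeps the ~10-11 Å charge anchors of the benchmark
  inside the sum while truncating negligible tails (with ε(r)=4r a unit-charge
  pair at 12 Å contributes < 0.6 kcal/mol).
* **Contacts**: residue pairs with any inter-part heavy-atom distance
  ≤ 4.0 Å, reported with the minimum distance.
* **Hydrogen bonds**: donor-acceptor ≤ 0.35 nm and hydrogen-donor-acceptor
  angle ≤ 30°, evaluated per frame; occupancy is the percentage of frames
  (reported to 0.01%). Donors without hydrogens fall back to
  antecedent-donor-acceptor ≥ 120° at ≤ 3.5 Å and are flagged `inferred`.
* **Trajectory statistics**: per-frame best-fit (Kabsch) RMSD to a reference
  frame; RMSF as the per-atom RMS deviation from the mean structure after
  per-frame superposition.

## Alanine scanning

For every residue appearing in the 4.0 Å contact table, side-chain atoms
beyond Cβ are removed (no repacking), the residue is re-typed as alanine, and
ddg_proxy = E(mutant) − E(wild type). Destabilizing mutations are positive;
residues with ddg_proxy ≥ 1 kcal/mol are hotspots. Glycine and proline are
reported not-scannable; alanine is a fixed point (ddg = 0). This is a
deterministic energy-difference proxy: it identifies which side chains carry
the interface under this package's energy model, and its values are not
expected to match trained alanine-scanning energy functions.

## Selection

Survivors are scored with interaction energy and interface ASA. "Largest
binding energy" means most negative energy. The joint rule selects the pose
maximal in both keys when one exists; otherwise the pose with the lowest sum
of the two ranks (recorded in the rationale). Ties break toward the lower
pose id. Stage survivor counts are non-increasing by construction, and a
stage that empties the candidate list is reported (`emptying_stage`), not
raised.

## Synthetic benchmark

The generator builds, deterministically per seed:

* **Receptor**: two 12-residue glycine helix rods (walls) along y at
  x = ±7.5 Å, carbonyls axial so the tube surface is smooth; an extended
  13-residue peptide in the groove (3.4 Å rise, register labels P-2..P11
  with P1 the third residue; flanking residues drape down over the platform
  edge); Asp/Glu anchors at P4/P6 buried downward, a Ser at P5 pointing up;
  and a β-sheet-like glycine floor under the groove so the receptor interior
  is solid (penetrating poses hit core cells). 473 atoms.
* **Probe**: a ~60-residue domain whose underside is a raft of two glycine
  rods lying parallel along the wall tops (long conformal line contacts),
  with three downward CDR-like prongs — CDR1/CDR2 apexes (residues 15/33)
  reaching into the groove within 4.5 Å of both walls, and a CDR3 prong
  whose Arg51 guanidinium hovers over the peptide (the electrostatic anchor)
  and whose Ser52 donates the planted hydrogen bond to the P5 Ser OG
  (D-A 2.90 Å, angle 0°). A varied capping helix (residues 54-60) sits
  > 10 Å from the receptor for locality checks. 332 atoms.

Design rationale for the planted features:

* The walls are exactly as long as the probe rods, so sliding along the
  groove loses contact length — this pins the shape-score optimum at the
  native translation. The peptide-flanking drape removes a spurious shape
  attractor the naked peptide overhang would otherwise create.
* The "salt bridge" is a *split* electrostatic anchor: the Arg sums
  interactions with two buried carboxylates ~10.5 Å away, each contributing
  ~0.6-0.8 kcal/mol. The Arg therefore exceeds the 1 kcal/mol hotspot
  threshold while each partner alone stays below it, making the Arg the
  unique hotspot; a literal 3 Å ion pair would make both partners hotspots.
* Coordinates carry 0.02 Å Gaussian jitter (planted atoms frozen) to avoid
  accidental lattice degeneracies; trajectory noise defaults to 0.3 Å, below
  the hydrogen-bond criterion margins so planted occupancies survive noise.

What the benchmark does *not* emulate: real side-chain rotamers and packing
density, sequence realism, backbone hydrogen-bonding networks, solvation,
and the size (~10× fewer atoms) and surface ruggedness of real p/MHC-TCR
interfaces. Passing the planted-recovery tests shows the pipeline's stages
are implemented and composed correctly — not that the scoring functions
would rank real TCR poses correctly.

## Problem sizes and runtime

The reference docking condition is a 64³ grid at 1.0 Å with 15° rotations
(6384 rotations, padded FFTs at 108³), about 4 minutes on one core; the
pipeline-recovery study uses 20 decoy seeds × 150 decoys with 400-point ASA
sampling. Unit tests use coarser grids (48³, 1.5 Å, 60°) where the docking
result itself is not under test.

## Known limitations

* Shape scores are sensitive to sub-cell grid alignment (±10%); the
  planted-native recovery criterion asks for top-100 membership, not rank 1.
* The probe raft has an approximate two-fold symmetry; 180°-flipped poses
  score close to native and legitimately populate the top ranks.
* The energy model has no hydrogen-bond term: a planted ideal H-bond scores
  slightly repulsive in LJ, which is visible as a small negative ddg_proxy
  for the donor serine.
* Multi-model PDB frames must be congruent (same atoms in the same order);
  alternate locations other than blank/'A' are dropped; insertion codes are
  carried but constraints address residues by number only.
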