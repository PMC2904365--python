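# groovedock

Rigid-body docking and interface analysis for T-cell-receptor-style
recognition of peptide-MHC surfaces.

When a T cell receptor (TCR) variable domain docks onto a peptide presented
in the groove of an MHC class II molecule, the binding mode is constrained by
well-known biology: the CDR1/CDR2 loops sit over the MHC helices, and the
CDR3 loop folds over the central positions of the bound peptide. `groovedock`
implements the computational workflow that exploits those constraints to
build and select a ternary-complex model:

1. **FFT shape-complementarity docking** (Katchalski-Katzir grid
   correlation): the receptor is digitized onto an N³ lattice with surface
   cells scoring +1 and core cells a negative penalty ρ; the probe scores 1
   where it occupies. For each rotation of a deterministic Euler sweep, the
   correlation over all translations is evaluated with forward/inverse FFTs,
   and the best-scoring placements are pooled:

   S(t) = Σ_c  A(c) · B(c − t)

2. **Coulombic binary filter**: poses with repulsive total electrostatic
   energy (distance-dependent dielectric, ε(r) = 4r) are discarded.
3. **Distance-constraint filter** in a compact notation — `30D:A 30D:B 50D:A
   50D:B (97-98)D:P` reads "residues 30 and 50 of probe chain D within the
   cutoff of chains A and B; residues 97-98 within the cutoff of peptide
   chain P" (default cutoff 4.5 Å, strict inequality).
4. **Peptide-register filter**: the pose survives only if the peptide residue
   nearest the CDR3 apex carries an allowed register label (e.g. P5/P6).
5. **Interface rescoring and selection**: buried interface area
   (ASA(A) + ASA(B) − ASA(A∪B), Shrake-Rupley-style golden-spiral sampling)
   and pairwise 6-12 Lennard-Jones + Coulomb interaction energy; the selected
   model maximizes both energy magnitude and interface area (rank-sum
   fallback when no pose dominates both).

Around the selection pipeline the package provides hydrogen-bond detection
with per-frame occupancy over multi-model trajectories (donor-acceptor
≤ 0.35 nm, H-donor-acceptor angle ≤ 30°), van-der-Waals contact tables
(≤ 4.0 Å), per-frame RMSD / per-atom RMSF, and a simplified computational
alanine scan that flags interface hotspots (ΔΔG proxy ≥ 1 kcal/mol upon
side-chain truncation).

Everything is exercisable without downloads: `groovedock.synthetic` generates
a deterministic toy receptor (two helical walls, a groove-bound 13-mer
peptide with register labels, a β-sheet-like floor) and a ~60-residue probe
domain with CDR-like loops, with a planted native pose, hydrogen bond,
electrostatic anchor and hotspot recorded in a truth manifest.

## Worked example

```python
import groovedock as gd

bench = gd.make_benchmark(gd.BenchmarkSpec(seed=7))
receptor, probe = bench.receptor, bench.probe

# dock and keep the 100 best poses by shape score
params = gd.DockParams(grid_dim=64, resolution=1.0, rotation_step=15.0,
                       n_poses_kept=100)
poses = gd.dock(receptor, probe, params, seed=7)
print(len(poses), poses[0].shape_score)

# filter by the planted two-step constraints and the P5/P6 register rule
survivors, report = gd.apply_constraints(poses, receptor, probe,
                                         bench.constraint_set(), mode="staged")
print(report["stage_counts"])

# interface characterization of the native complex
print(round(gd.interface_asa(receptor, probe), 1))
print(round(gd.interaction_energy(receptor, probe), 2))

scan = gd.scan_interface(receptor, probe, threshold=1.0)
print(scan.hotspots()[["chain", "residue_number", "ddg_proxy"]])
```

Output (seed 7):

```
100 209
{'input': 100, 'receptor-facing': 2, 'peptide-facing': 2}
929.9
-43.61
  chain  residue_number  ddg_proxy
0     D              51   6.563252
```

Reading: docking retains 100 candidate placements (best raw correlation
score 209); the two-step distance constraints cut them to 2 near-native
orientations; the native complex buries ~930 Å² of surface with an
interaction energy of −43.6 kcal/mol; and the alanine scan identifies
exactly one hotspot — the planted CDR3 arginine anchor (ΔΔG proxy
6.6 kcal/mol ≥ 1).

A command-line interface mirrors the library:

```bash
groovedock make-benchmark --seed 7 --out bench/
groovedock dock --static bench/receptor.pdb --mobile bench/probe.pdb \
    --grid-dim 64 --resolution 1.0 --keep 100 --out poses.tsv
groovedock filter --static bench/receptor.pdb --mobile bench/probe.pdb \
    --poses poses.tsv --constraints "15D:A 15D:B 33D:A 33D:B (51-52)D:P" \
    --cutoff 4.5 --out surviving.tsv
```

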