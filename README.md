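# helixgraft

Tools for designing and evaluating **scaffold-grafted antigens**:
chimeric proteins in which a short α-helical epitope from a membrane
protein (for example, the extracellular helix of a glucose transporter,
residues 35–54 or 35–69) is transplanted into the variable loop of a
hyper-stable display scaffold so the fragment keeps its native
conformation and can raise conformation-specific antibodies.

The hard question in such designs is not making the chimera — it is
knowing whether the grafted segment *stays helical* and *which contacts
hold it in place*. `helixgraft` answers that with four quantitative
readouts over structural ensembles plus a differential HDX-MS analysis
of binder epitopes:

1. **Graft construction** — excise a scaffold loop, size flexible
   linkers from the mismatch between the donor's Cα end-to-end span and
   the scaffold anchor gap (`2·n·3.5 Å ≥ |Δ| + 4 Å`, capped at 10 per
   side), assemble the chimera sequence with a position-by-position
   index map back to scaffold/linker/donor, and build a crude
   rigid-placement, clash-checked starting model.
2. **Helix assignment** — per residue, per frame, from the
   Kabsch–Sander backbone hydrogen-bond energy
   `E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol (bond when
   `E < −0.5`); residues *i+1..i+4* are α-helical when 4-turns exist at
   both *i* and *i+1*. The headline statistic is the helical fraction
   over frames × interior segment residues (two residues excluded per
   terminus), mean ± sd over three replicates.
3. **Segment RMSD** — Kabsch least-squares superposition (SVD with
   proper-rotation correction) and the per-frame Cα RMSD of the grafted
   segment's interior against a reference structure.
4. **Pair energetics** — the symmetric residue-pair matrix of
   frame-averaged Coulomb + Lennard-Jones energies
   (`332.0636 q_a q_b / r + ε[(r_min/r)¹² − 2(r_min/r)⁶]`, 12 Å
   truncation, ε_combining by geometric mean), with cells classified as
   covalent-adjacent diagonal, i→i+4 hydrogen-bond band, hydrophobic
   core, or other; inter-helix contributors are ranked by summed
   cross-helix energy, and alanine-truncation mutants quantify what a
   stabilizing aromatic contributes.
5. **HDX-MS epitope calls** — per-peptide deuterium-uptake differences
   Δ(t) = bound − apo; peptides with Δ ≤ −0.05 at ≥ 2 timepoints are
   flagged and annotated (grafted / scaffold / linker / mixed) through
   the design's index map.

Everything is testable without external data: the `synthetic_data`
module generates ideal-geometry helices, a toy two-helix scaffold with
an excisable VVAG loop, replicate helix-fraying trajectories whose
per-residue helicity follows a calibrated Zimm–Bragg two-state model,
a planted-aromatic two-helix bundle, and HDX uptake tables with a
planted, binder-protected epitope — all seed-deterministic.

## Worked example

```python
from helixgraft import RunConfig, run_design_evaluate

report = run_design_evaluate(RunConfig(seed=1, n_frames=300))
print(report.summary_text())
```

prints

```
config hash: d74bf18d12228c37
chimera: 62 residues (GGGS/GGGS linkers, donor D:35-54)
helicity over A:1-20: 84.4% (±1.3%) across 3 replicates
segment RMSD: 2.14 ± 0.03 Å over 16 Cα
top inter-helix contributors: 11 (-7.4), 4 (-7.0), 8 (-7.0)
cross-helix energy: -21.4 kcal/mol
triple-alanine control: cross-helix 0.0 kcal/mol (Δ = +21.4)
HDX: 5 protected peptide(s), regions: grafted, mixed
```

Reading this: a 20-residue donor helix was grafted into the toy
scaffold's loop between two auto-sized GGGS linkers (62-residue
chimera).  Across three simulated replicates calibrated to 85% target
helicity, 84.4% of interior (frame, residue) observations were
α-helical, and the grafted segment stayed within 2.1 Å Cα RMSD of the
ideal helix over its 16 interior residues.  In the two-helix bundle
fixture the three planted aromatic anchors (residues 4, 8, 11) are the
top inter-helix contributors; truncating them to alanine removes the
entire −21.4 kcal/mol cross-helix stabilization — the computational
analogue of a triple-alanine mutant losing its helical conformation.
The simulated HDX experiment flags protected peptides covering the
grafted region.

The same stages are available piecewise from the shell:

```bash
helixgraft simulate fray --seed 3 --out fx/ --target-helicity 0.7
helixgraft ss --segment A:1-25 --pdb fx/fray_rep0.pdb --pdb fx/fray_rep1.pdb --pdb fx/fray_rep2.pdb
helixgraft rmsd --traj fx/fray_rep0.pdb --ref fx/fray_rep0.pdb --segment A:1-25
helixgraft energy --traj fx/two_helix_bundle.pdb --segment A:1-17 --out matrix.csv
helixgraft hdx --apo apo.csv --bound bound.csv
helixgraft run --seed 1 --out run1/
```

## Layout

| module | contents |
| --- | --- |
| `helixgraft.structure_io` | structures, ensembles, segments; PDB/CSV I/O |
| `helixgraft.graft_design` | loop excision, linker sizing, chimera assembly, initial model, alanine truncation |
| `helixgraft.secondary_structure` | amide-H placement, Kabsch–Sander energies, helix assignment, helicity statistics |
| `helixgraft.superpose_rmsd` | Kabsch superposition, segment Cα RMSD series |
| `helixgraft.energetics` | nonbonded parameters, residue-pair energy matrices, bands, contacts, contributors |
| `helixgraft.hdx_diff` | uptake tables, differential analysis, epitope calls |
| `helixgraft.synthetic_data` | all synthetic generators (deterministic, ground-truth-labeled) |
| `helixgraft.pipeline` / `helixgraft.cli` | end-to-end orchestration and the `helixgraft` command |

See `docs/methods.md` for the models, conventions and limitations.
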