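# Methods

This note documents the models and conventions behind `helixgraft`: what
each operator computes, the defaults and why, what the synthetic
generators do and do not emulate, and the numerical choices a user
re-deriving a result would need.

## Coordinate and numbering conventions

Author (PDB) residue numbering is used everywhere, and all residue
ranges are inclusive on both ends, so "segment 35–54" has 20 residues
and its interior after the standard two-per-terminus exclusion has 16.
Chimeras are renumbered sequentially from 1; the design's index map
retains the source numbering so results can be reported in donor
coordinates.  Multi-MODEL PDB files map to coordinate frames over one
topology; the default frame spacing is 10 ps.  HETATM records and
waters are skipped on input; for alternate locations the
highest-occupancy conformer is kept (ties by altloc letter).  A
single-frame ensemble is written without MODEL records, a multi-frame
one always with them.

## Helix assignment

Backbone amide hydrogens are placed geometrically whenever absent:
`H_i = N_i + 1.0 Å · unit(C_{i−1} − O_{i−1})`, skipping prolines and
chain starts.  The hydrogen-bond energy is the Kabsch–Sander
electrostatic model, `E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
kcal/mol with distances in Å, clamped below at −9.9 and returning +∞
when any distance is under 0.5 Å (overlapping atoms); a bond exists
when `E < −0.5` kcal/mol.  A 4-turn at *i* is a bond from C=O(*i*) to
N–H(*i+4*); residues *i+1..i+4* are labeled H when turns exist at both
*i* and *i+1*; everything else (including 3₁₀/π helices and strand) is
C.  Only the two-class alphabet is produced because every statistic of
interest is "fraction in α-helical conformation"; counting 3₁₀/π as
helical would raise fractions slightly on frayed ends.

The helical fraction of a segment is the occupancy average: H-labeled
(frame, residue) pairs over frames × interior residues, computed per
replicate, with mean and sample standard deviation (n−1) across
replicates (default 3).  The alternative per-residue-then-average
reading is computed alongside; for complete data the two are
identical, and both are reported.

## Superposition and segment RMSD

Kabsch superposition minimizes `Σ|R·p + t − q|²` via SVD of the
covariance matrix with the usual determinant sign correction, so the
returned rotation is always proper (no reflections); degenerate
(collinear, N < 3) inputs are rejected.  The RMSD contract is: per
frame, superpose on the fit selection's Cα atoms, then measure RMSD
over the interior segment Cα atoms.  The default fit selection is the
interior segment itself (self-fit), which measures internal
conformational change of the grafted region — the helix-stability
question — rather than rigid-body motion relative to the scaffold; a
`fit_on` override selects any other region.  Time axes are frame index
× frame spacing.

## Residue-pair energetics

Nonbonded energies use an embedded, deliberately simple parameter set
(charges in e, LJ in kcal/mol and Å) covering every standard
heavy atom plus the backbone amide hydrogen: CHARMM-style backbone
charges (N −0.47, H +0.31, CA +0.07, C +0.51, O −0.51), seed charges on
polar side-chain atoms, and the residual placed on CB (CA for glycine)
so every residue sums exactly to its formal charge.  Nonpolar
hydrogens are not modeled.  Amide hydrogens are placed geometrically
before any evaluation — without them every residue would carry a
spurious −0.31 e monopole.  LJ parameters are assigned by atom class
(aliphatic/aromatic/carbonyl carbon, nitrogen, carbonyl/hydroxyl
oxygen, sulfur, amide H).  No claim of bit-compatibility with any
published force field is made; the contract is the qualitative band
structure of the pair matrix.

The pair energy is `Σ 332.0636 q_a q_b / r + ε_ab[(rmin_ab/r)¹² −
2(rmin_ab/r)⁶]` over atom pairs with `r ≤ 12 Å` (plain truncation, no
switching, no long-range correction, dielectric 1).  For
sequence-adjacent residues the five atom pairs one or two bonds across
the peptide bond (C–N, CA–N, O–N, C–CA, C–H) are excluded; there is no
1-4 scaling.  Matrices are frame-averaged (stride selectable), strictly
symmetric, with the self-diagonal NaN.  Band labels: |i−j| = 1 →
`adjacent`; Kabsch–Sander bond in ≥ 50 % of frames and |i−j| ∈ {3,4,5}
→ `hbond_band`; both residues in the hydrophobic set
{A,V,L,I,M,F,W,Y,P} with frame-averaged total ≤ −1.0 kcal/mol →
`core`; else `other`.  Hydrophobic contacts use minimum side-chain
heavy-atom distance ≤ 4.5 Å (CA for glycine).  Inter-helix contributors
are ranked by summed cross-helix pair energy, most negative first, ties
by residue index; because each pair energy accrues to both partners, a
residue only ranks above its contact partners by touching several of
them.

Plain atom-pair truncation has a known artifact: it slices neutral
charge groups at the cutoff boundary, leaving net-monopole noise of a
few kcal/mol between residues near 12 Å separation.  This is inherent
to the stated convention and is why the planted-signal fixture (below)
is built the way it is.

## Graft construction

Linker sizing uses two canonical geometry constants: helix rise
1.5 Å/residue (so a donor of n residues spans ≈ 1.5(n−1) Å) and
extended-linker reach 3.5 Å/residue.  The recommended per-side linker
length is the smallest n with `2·n·3.5 ≥ |donor span − anchor gap| +
4.0 Å` of slack, capped at 10 with a warning.  The initial model keeps
scaffold coordinates outside the excised loop bit-exactly, aligns the
donor's termini axis with the anchor axis, places the termini midpoint
on the anchor midpoint displaced outward along the loop normal, and
searches outward standoffs (4–8 Å in 1 Å steps) × rotations about the
anchor axis (10° steps), taking the first pose with no inter-segment
heavy-atom pair under 2.0 Å; failure raises an error listing the
offending pairs.  Linkers are laid on a spiral detour around the
anchor–donor chord (envelope pinned at both ends), with amplitude,
winding and phase searched until the crude per-bead backbone clears
everything it is not bonded to.  The result is explicitly a starting
model, not a structure prediction.  Alanine truncation sets the residue
name to ALA and deletes side-chain atoms beyond CB; backbone atoms are
never touched, glycines are left unchanged with a warning, and the
operation is idempotent.

## Synthetic generators: what they emulate, and what not

**Fraying trajectories.**  Latent per-residue helix/coil states evolve
by checkerboard Gibbs sweeps under a Zimm–Bragg chain: a helix site
carries propagation weight *s*, starting a run costs the nucleation
weight σ (default 0.05).  Coordinates realize helical stretches with
ideal torsions (φ=−57°, ψ=−47°), coil stretches with broad non-helical
torsions (φ ∈ U[−180°,−100°], ψ ∈ U[100°,180°]), built by
internal-coordinate chain construction with ideal bond geometry, plus
Gaussian coordinate noise (default σ = 0.05 Å).  In this realization a
4-turn at *i* prints through exactly when latent states *i+1..i+3* are
helical (ψ_i rotates O_i together with the downstream chain, so state
*i* itself does not matter), so the hydrogen-bond assignment sees a
latent run wherever a 4-long all-helix window with 1 ≤ k ≤ n−5 covers
the residue.  The propagation weight is calibrated by bisection against
the *exact* transfer-matrix expectation of this assignment-visible
helicity over the interior residues, so the measurable statistic hits
the target by construction.  Defaults mirror the analysis conventions:
3 replicates, 10 ps spacing, 2-residue terminal exclusion, 25 residues,
2000 frames.  The simulator is kinematic: no forces, no solvent, no
kinetic realism — its purpose is ground-truth-labeled ensembles for
validating the analysis operators, and passing its tests says nothing
about force-field accuracy on real trajectories.

**Toy scaffold.**  A deterministic 38-residue helix-loop-helix chain
numbered 30–67 with an excisable VVAG loop at 47–50, built from fixed
torsions; the loop torsions were hand-tuned once so the helices run
antiparallel, the anchor Cα gap is ≈ 10.3 Å and no heavy-atom pair
comes under ≈ 3 Å.

**Planted-anchor bundle.**  Two antiparallel ideal helices (residues
1–17 and 21–53 of one chain) with aromatic anchors Trp4, Trp8, Tyr11 on
helix A.  This is an *abstract* planted-signal fixture, not a packed
coiled coil: under the vacuum-electrostatics + truncation convention,
backbone–backbone Coulomb terms between closely packed ideal helices
are several kcal/mol per residue and would drown any side-chain
contact signal.  The fixture therefore separates the helices beyond
the 12 Å cutoff (21 Å axis distance) and places the anchors' positively
charged ring atoms (CD1/CE2 of Trp, CZ of Tyr) as long reaching tips
near backbone carbonyls of helix B, each tip targeting a per-tip
energy (−3.5 kcal/mol for Trp tips, −7 for Tyr) split over two
carbonyls of distinct residues, with a running per-residue cap (−5.5
kcal/mol) so no helix-B partner can outrank an anchor.  By
construction the three anchors are the dominant inter-helix
contributors and alanine truncation removes essentially the whole
cross-helix energy.  Tip placement is a deterministic grid search;
regeneration is bit-identical.

**HDX tables.**  Per-residue uptake follows `u(t) = 1 −
exp(−k_int·t/PF)` with log-normal intrinsic rates (median 1 s⁻¹) and
apo protection factors (median 50); binding multiplies PF by the
fold-change (default 10) on epitope residues only.  Peptide uptake is
the mean over exchangeable amides (every residue after the peptide's
first, excluding prolines), with Gaussian noise (sd 0.01) clipped to
[0, 1].  The peptide map is 8-residue windows stepped by 5 — typical
peptic peptide sizes — chosen so that a peptide overlapping the
epitope by even a single amide still carries a detectable share
(≥ 1/7) of the protection signal; with 10-residue windows such
boundary peptides fall below the calling threshold and recovery of the
planted mask is not reliable.  The generator does not model EX1
kinetics, back-exchange gradients, overlapping charge states or
peptide misassignment.

## HDX differential analysis

Δ(t) = bound(t) − apo(t) per matched peptide (matched on range and
sequence), summary = mean over timepoints.  A peptide is called
protected when Δ ≤ −0.05 at ≥ 2 timepoints; both thresholds are
tunable and the raw differences are always reported next to the calls.
These defaults are simple operating points, not statistical tests; an
optional Welch t-test over replicates with Benjamini–Hochberg
adjustment is available and off by default.  When a mass triplet is
supplied instead of fractions, uptake is normalized as
`(m_t − m_0)/(m_full − m_0)`.

## Problem sizes and tolerances

The shipped validation runs use: 1000 random instances for the
superposition oracles (rotation recovery to 1e−6, RMSD identity to
1e−9), 1000 random geometries for the hydrogen-bond energy oracle
(1e−9), 30 random full-atom residue pairs for the pair-energy double
loop (1e−9 with a 1e−12 relative floor for hard-clash magnitudes),
fraying recovery at 3 replicates × 2000 frames × 25 residues per
target (±0.05 on the recovered fraction, ±0.03 on per-observation
agreement with ground truth), a 16-site chain × 4000 Gibbs samples for
the transfer-matrix cross-check, and 200-frame pipeline runs for the
determinism check.  These sizes make the whole suite and the
acceptance script each complete in about a minute on one CPU while
keeping the Monte-Carlo error well inside the asserted bounds.

## Known limitations

* The nonbonded model is a documented simplification: vacuum
  dielectric, truncated electrostatics, no nonpolar hydrogens, no
  bonded terms.  Band patterns and relative rankings are meaningful;
  absolute energies are not comparable to any published force field.
* The initial-model builder does no loop closure, rotamer packing or
  refinement; its output is a clash-free starting point only.
* Helix assignment is strict two-state α/other; 3₁₀ and π content is
  counted as coil.
* The fray simulator's coil ensemble is a single broad torsion basin;
  real coil states are heterogeneous, so coordinate-level statistics
  other than helicity (e.g. radius of gyration) are not realistic.
* PDB is the only trajectory format in core; binary formats would go
  through an optional adapter, not the core reader.
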