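# Methods

## Helicity model

Residue-level secondary structure is assigned from backbone dihedrals
alone: a residue is right-handed α-helical in a frame iff both φ and ψ fall
inside a rectangular window (closed intervals at the bounds). The default
window is φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]. These bounds are a design
choice of this package: they place the ideal α-helix (−57°, −47°) well in
the interior, exclude canonical β-strand and polyproline conformations, and
match a widely used published right-handed-helix criterion. Every reported
quantity that depends on the window carries the window used in its output
metadata, and all four bounds are configurable (`HelixWindow`, CLI
`--phi-min` etc.). No hydrogen-bond (DSSP-style) assignment is performed,
and 3₁₀/π classes are not distinguished; this is deliberate — the pipeline's
helicity timeline plays the role a DSSP plot would, from dihedrals only.

Angles follow the IUPAC sign convention, in degrees in (−180, 180], ties at
±180 reported as +180. A dihedral is undefined when a backbone atom is
missing, at chain termini, or when the peptide C–N distance to the adjacent
residue is ≥ 2.0 Å (configurable). The distance rule matters for
loop-deleted constructs such as the Bcl-X_L_ simulation construct, where
residue 44 is covalently linked to residue 85 in the model but deposited
coordinates may leave the gap open: a naive sequence-consecutive rule would
fabricate a dihedral across the gap.

Helical content of a frame = 100 × (helical residues) / (all residues of
the analysed chain). Residues with undefined dihedrals count in the
denominator only, so a 20-residue ideal helix scores 90%, not 100%. This
whole-chain denominator is the reading of "fraction of residues having
helical conformation" adopted here.

## Stable and consensus segments

Per-residue occupancy is the fraction of analysed frames in which the
residue is helical. A *stable helical segment* is a maximal run of at least
`min_len = 4` consecutively numbered residues, each with occupancy ≥
`occupancy_threshold = 0.80`. The threshold is non-strict ("at least 80%")
and stability is evaluated per residue before run decomposition — the
weakest reading consistent with the definition; whole-segment co-occurrence
would be stricter and is not used. A *consensus segment* is a maximal run
(≥ `min_len`) of residues that belong to a stable segment in at least
`min_sims = 2` of the replicate simulations ("at least two out of four" is
non-strict).

## RMSD

Superposition uses the closed-form Kabsch/SVD solution restricted to proper
rotations (a reflected solution is never returned, since physical rigid
motion cannot reflect). The RMSD series fits each frame's selected Cα set
onto the same selection of the reference before measuring — the fit and the
measurement use the same atoms. Residues missing a Cα in either structure
are excluded from the selection. No mass weighting, no iterative trimming.

## Contacts

Two residues interact when their minimum heavy-atom distance is < 4.0 Å
(strict). The census over structures is a union across structures of pairs
whose residues (a) lie in different allowed regions (helices H1–H6, loops
LB/LC/LD by default), and (b) are at least `min_seq_sep = 3` apart in
sequence. The separation default suppresses trivially adjacent
region-boundary contacts; because the published 174-pair census does not
state an exclusion, the parameter is exposed and the census's sensitivity
to it should be reported alongside the count. Persistence over a window is
the fraction of frames below the cutoff; stability requires persistence
> 0.5 (strict, "more than 50%") in ≥ 2 replicates. Windows are time ranges
resolved against the frame spacing and include the boundary frame at the
window start.

Whole-structure pair search uses a k-d tree over heavy atoms; per-pair
distance traces use a vectorised all-pairs minimum. At typical residue
sizes (≤ 15 heavy atoms) the all-pairs kernel is exact and fast, so no
cell-list acceleration is used; tests verify both paths against an
explicit double-loop oracle.

The destabilisation scan reports, within a given helix: glycine positions,
and like-charged pairs — acidic (D/E with D/E) or basic (K/R with K/R) — at
sequence separation exactly 3 or 4. Residues spaced 3–4 apart sit on the
same helix face, so such pairs repel; together with a helix-breaking
glycine these are the classic sequence features of an unstable helix.

## SASA

Shrake–Rupley numerical quadrature: per heavy atom, points on a
golden-spiral lattice at radius (r_vdW + probe); a point is occluded if it
lies inside any other included atom's probe-expanded sphere; atom SASA =
accessible fraction × 4π(r + probe)², residue SASA = sum over its atoms.
Defaults: probe 1.4 Å (water), 960 points, Bondi-type per-element radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å, …). Hydrogens are excluded throughout —
simulation structures often carry polar hydrogens only, and including a
variable hydrogen complement would bias areas. Because the radii set behind
published g_sas-era values is not recorded, absolute Å² values are
comparable only to method tolerance; outputs should be read together with
the radii-set name, which the run manifest records.

Quadrature noise per residue scales as ~1/√n_points and is about 1% at the
default 960 points (an independent Shrake–Rupley implementation shows the
same); halving below 0.5% requires ≳ 4000 points. The convergence test
therefore asserts the <0.5%-on-doubling property from 3840 points, and
cross-implementation agreement is checked at converged point counts.

Burial by a region: per frame, residue SASA is computed twice — full
structure, and with all mask-region atoms removed — then window-averaged;
buried = avg(without) − avg(with), which is non-negative up to quadrature
noise since removing atoms cannot reduce exposure. Windowed exposure tables
label a residue *buried* when its window-averaged SASA is below
`threshold_A2` (default 40 Ų). The published tables mark buried residues
typographically without defining the criterion, so the threshold is an
exposed parameter with no literature-backed default; 40 Ų sits between the
buried and exposed clusters those tables show for bulky hydrophobics.

## Synthetic trajectories

The generator emulates the features the analyses consume, not the physics
that produced them:

* per-residue dihedral regimes — helical mean (−57°, −47°) or coil mean
  (−80°, 150°), Gaussian noise (helical σ defaults 4–6°, coil σ 25°), with
  an optional switch frame after which a residue samples its second regime
  (scheduled unwinding);
* chains rebuilt each frame from internal coordinates (NeRF recurrence,
  ideal bond lengths/angles, ω = 180°), atoms N/CA/C/O plus Cβ for non-Gly;
* rigid per-chain placements, optionally switching mid-run (a shielding
  chain moving over a groove residue);
* contact schedules: a per-frame Bernoulli draw decides whether a mobile
  chain is translated so a designated residue pair sits at 3.5 Å (contact)
  or 9.0 Å (separated), straddling the 4 Å rule.

All randomness derives from the spec's seed; identical specs yield
bit-identical trajectories and manifests. The manifest records the helicity
mask implied by the regime means (chain termini non-helical), the stable
segments derived from it, the realised contact draws, and the placement
switch events.

What the generator does **not** emulate: force-field energetics, thermal
kinetics, frame-to-frame continuity (each frame is an independent rebuild),
side chains beyond Cβ, solvent, or cooperative unfolding. Passing the
recovery tests therefore demonstrates that the analysis operators compute
their definitions correctly on data with known truth — not that the
pipeline would reach the same biological conclusions on any particular real
trajectory.

Study conditions used by the tests and the acceptance script: the
4-replicate consensus fixture runs 4 × 300 frames over a 76-residue chain
(programmed helical regions 5–20, 26–40, 46–60, 64–72; region 26–40
unwinding at 40% of the run in replicates 1–3); contact recovery uses a
0.70-probability schedule over 2000 frames (binomial SE ≈ 0.010, so the
±0.03 check is a 3σ bound); occupancy recovery uses 1000 frames with the
switch at 40%; the shielding fixture uses 20 frames (SASA is the expensive
stage) with 480-point quadrature.

## Numerical and degenerate-input choices

* Kabsch with N = 3 collinear points still returns a minimising proper
  rotation (SVD sign correction);
* exact ties at a dihedral of ±180° report +180°;
* altloc records resolve to the highest-occupancy conformer on read;
  waters and ions are dropped; hydrogens are kept but flagged non-heavy;
* residue numbering is taken verbatim from the input files (UniProt Q64373
  frame for Bcl-X_L_); intervals are 1-based inclusive everywhere;
* the shipped region map keeps regions disjoint (LC = 134–136, LD = 158);
  published usage sometimes counts M159/L162 as "LD" while also listing
  159–185 as H5 — with disjoint defaults those residues report as H5, and
  users who prefer the looser LD can supply their own region map;
* empty selections, empty windows, inconsistent residue axes and
  overlapping mask/target sets raise typed errors rather than returning
  empty results.

## Known limitations

* The dihedral-window assignment is blind to hydrogen-bond topology: an
  isolated residue with helical φ/ψ counts as helical even with no helix
  around it (the ≥4-run rule recovers most of the difference at segment
  level).
* SASA is quadrature-based, not analytic; per-residue values carry ~1%
  noise at default settings.
* The contact census depends on the region map and the sequence-separation
  setting; counts should always be reported with both.
* Trajectory reading loads all frames into memory; trajectories far beyond
  ~10⁵ frames × 10³ atoms would need chunking that is not implemented.
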