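# Methods

## The system and the model

Human HtrA2(Omi) is a homotrimeric mitochondrial serine protease whose
subunits pair a chymotrypsin-fold protease domain (PD, residues ~150–343
in author numbering) with a C-terminal PDZ domain (~359–458) through a
flexible linker (344–358, unresolved in the inactive-state crystals). In
the inactive state the PDZ forms a tight lid over the PD, held by two
clusters of hydrophobic interface residues — hinge A,
(β11-L2-β12)_PD : (β14-α5)_PDZ, and hinge B, (β5-LC-β6)_PD : (β13/α7)_PDZ.
Activation models posit a rigid-body rotation of the lid about these
hinges. This package treats that motion as a measurement problem: given
structures or Cα trajectories, quantify the lid rotation, the interface
opening, the hinge contacts, and the catalytic readiness of the
His198/Asp228/Ser306 triad.

## Superposition and the two-stage motion fit

Rigid superposition is the Kabsch algorithm in SVD form with the standard
determinant correction (the smallest singular direction is flipped when
needed), so only proper rotations are returned; collinear point sets raise
an error rather than returning an arbitrary rotation. Weighted fits are
supported but default to uniform weights, matching how Cα RMS values are
conventionally reported. Residue pairing between structures uses chain id
and author residue number only — never the residue name — so point mutants
pair with their parent structure.

Per frame, the lid motion is extracted in two stages: (1) the frame is
superposed onto the reference over PD Cα only, removing global motion;
(2) the reference PDZ Cα are superposed onto the PD-aligned frame's PDZ
Cα. The stage-2 transform is the reported PDZ-vs-PD motion, and its
direction follows the physical displacement of the lid (reference →
frame). Stage 2's residual RMSD is reported as the lid's internal
deformation; it is exactly zero when the lid moves rigidly. A screw-axis
decomposition of the raw frame-to-frame transform would mix global and
interdomain motion; the two-stage fit pins the analysis to the PD frame
of reference and is deterministic.

**Sign convention.** The rotation is converted to axis–angle form and the
axis is oriented so that its dot product with a topology-defined reference
vector (Cα331→Cα343 by default, approximating the N→C direction of the
C-terminal PD helix α4) is non-negative; the angle carries the sign of
that orientation. Positive is labelled `cc` (counterclockwise for a viewer
looking along the reference direction with the PD C-terminal barrel in
front), negative `c`, and magnitudes strictly below the threshold
(default 10°, the smallest labelled rotation in the motivating
simulations) are `i` — minute irregular motion. Exactly at the threshold
the label follows the sign. The distinction that a `c` rotation axis
passes near the peptide-recognition motif rather than between the
terminal helices is approximated by the sign alone; users needing the
axis itself get it per frame.

**Opening distance.** Δ is the instantaneous Cα–Cα distance of the
reporter pair I179(β2)–L398(β15), residues close to the maximal radius of
the lid motion. It is reported as a distance, not a difference from the
start; the closed-state value in the deposited inactive structure is
~8 Å. Both the pair and the threshold are topology parameters.

## Contacts and the catalytic triad

A contact is a residue pair whose minimum inter-atomic distance over
heavy atoms is ≤ cutoff (default 3.5 Å); a side-chain-only scope is
available. The engine uses a KD-tree and is tested against a brute-force
all-pairs oracle. Hinge contacts are the same computation restricted to
the hinge A and hinge B residue sets of the topology, computed
independently.

Triad competence requires all five criterion distances inside their
bands: Oγ(Ser)–Nε2(His) 3.15 ± 0.2 Å; Nδ1(His)–Oδ(Asp) 3.3 ± 0.4 Å (the
minimum over Oδ1/Oδ2 — the carboxylate oxygens are chemically equivalent,
a deliberate widening of the single-oxygen formulation); and the Cα
triangle 8.6 ± 0.1, 6.5 ± 0.1, 10.2 ± 0.1 Å. The printed halfwidths are
treated as hard acceptance bands and are configurable. A serine lacking
Oγ (the Ser→Ala crystallization mutant) yields the verdict
`non_evaluable` rather than `incompetent`: the His–Ser criterion cannot
be measured, and conflating "cannot measure" with "fails" would
mislabel every crystal form of this system.

## Essential dynamics (PCA)

Frames are aligned either on frame 0 or (default) on an iteratively
refined mean structure (mean → align → mean, until the mean shifts
< 1e-6 Å, at most 20 rounds), since segmental-motion profiles are
conventionally referenced to time-averaged coordinates. The covariance of
the mean-centred 3N Cα coordinates is diagonalized through the SVD of the
frames×3N matrix — algebraically identical to both the 3N×3N covariance
route and the frames×frames dual, and tested against a dense-covariance
oracle. Eigenvalues use the population convention (divisor = frame
count), so Σλ equals the mean squared deviation from the mean structure.
No mass weighting (Cα only, uniform). Only numerically zero singular
values are dropped, so projecting on all retained modes reconstructs the
aligned frames to machine precision. Per-residue square displacements of
mode k are λ_k·|v_j|² for the mode's 3-vector at residue j, summing to
λ_k over residues.

## The restraint model and rigid-body optimizer

The packaged restraint file transcribes nine Cα–Cα distance targets
between PD and PDZ residues, derived from tryptophan-quenching distance
tendencies for the opening transition, with force constant
k = 1 kcal mol⁻¹ Å⁻² each. The published constant is dimensionally
incomplete ("1 kcal/Å"); it is interpreted as the standard harmonic
constant with E = Σ k(d−d₀)², the usual squared-deviation form.

The reference computation behind the restraints was cryogenic restrained
dynamics with all backbone dihedrals frozen — i.e., the domains moved
essentially as rigid bodies. The package makes that explicit: the PD is
held fixed and the PDZ pose is optimized over its six rigid degrees of
freedom, minimizing restraint energy plus a soft-sphere clash penalty
Σ w(r₀−d)² over cross-domain Cα pairs with d < r₀ (r₀ = 2.5 Å,
w = 10 kcal mol⁻¹ Å⁻²). The unresolved linker is excluded from both
terms, and the clash term also excludes the loop stumps flanking the
sensor-loop gap (274–281 and 291–298 by default) — with them in place the
truncated loop ends sterically pin the lid shut, the same obstruction
that motivated truncating them in the original restrained runs.

The default optimizer is deterministic two-stage coordinate descent:
first a cheap restraint-only pre-solve, multi-started from a small fixed
set of lid orientations (identity and ±90° about each axis), locates the
essentially unique pose satisfying the nine distances; then the full
objective is descended once from that pose with a shrinking step schedule
(initial steps 0.2 rad / 2 Å, halved when a sweep yields no improvement;
stop when gains fall below 1e-6 kcal/mol over 50 iterations). Because the
pre-solve optimum is a property of the restraint set and the domain
shapes, not of the input lid placement, closed and artificially opened
starts converge to the same final distances — the package's counterpart
of start-independence in the original restrained runs. An optional
seeded simulated-annealing mode explores before the same descent polish.
The author-reported optimized distances for the real monomer are packaged
as reference data for report layout but are not reproduced by the
surrogate: a Cα-only rigid placement has different search dynamics than
all-atom restrained dynamics, so only the start-consistency property and
the analytic single-restraint optimum are asserted.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their seeds.

* **Two-domain scaffolds**: two compact quasi-uniform point clouds at
  protein-like density (~120 Å³ per Cα), separated by a configurable
  centroid distance, with a topology naming the domains, a linker gap, an
  interface-spanning opening pair, and a sign-reference pair. Globular
  clouds keep the inertia tensor well-conditioned, so domain fits are
  numerically stable for every seed — an elongated domain would make the
  rotation component about its long axis poorly determined.
* **Rotation trajectories**: the mobile domain is rotated per frame by a
  scheduled angle about a known (axis, pivot), then i.i.d. Gaussian noise
  of chosen σ is added to every coordinate. The defaults used in tests and
  in the acceptance script — 40–50° final angles, 50 frames, σ = 0.5 Å —
  mirror the magnitudes of the motivating simulation study (lid rotations
  of ~10–50° over 50 ns with snapshots every 1 ps; the package analyses
  trajectories at these desk-scale sizes rather than 50 000-frame runs).
* **Triad fragments**: the Cα triangle is embedded in a plane, the
  imidazole is an idealized planar pentagon oriented with Nε2 toward the
  serine and Nδ1 toward the aspartate, and Oγ/Oδ1 are placed to realize
  the requested distances exactly (Oδ1 on the intersection of the
  criterion sphere with a 2.5 Å reach sphere around the Asp Cα).
  Competent examples sample all five distances inside their bands;
  incompetent ones push ≥1 outside by up to a configurable spread.
* **HtrA2-numbered monomer**: domain clouds carrying the packaged residue
  numbering, with the restraint-anchor residues adjusted by joint least
  squares so an open pose satisfying all nine targets exactly exists; the
  returned structure is that geometry with the lid rotated to a closed
  pose. This makes the restraint optimum well-defined without pretending
  to real coordinates.

What passing on these fixtures shows: the estimators recover known rigid
motions to machine precision, degrade gracefully under isotropic noise,
and the restraint optimizer is start-independent when its optimum is
realizable. What it does not show: behaviour on real conformational
ensembles — correlated backbone motion, anisotropic B-factor structure,
domain plasticity, and trimer-packing effects are all absent from the
generators, and the deposited-structure regressions in the test suite are
the only checks against experimental coordinates.

## Structure I/O choices

Author numbering as deposited is used everywhere; nothing is renumbered.
Alternate locations keep the highest-occupancy conformer (ties broken by
altloc letter), making every distance deterministic. Hydrogens are
dropped (the target crystal structures contain none; all criteria are
heavy-atom). Waters and other heteroatoms are dropped unless requested —
peptide ligands deposited as separate chains of standard residues are
retained either way. Missing residues come from unresolved-residue
remarks when present; otherwise a single numbering offset is fitted per
chain between SEQRES and the resolved residues (accepted at ≥95% name
agreement); if neither source applies, the missing set is *unknown* and
querying it raises a distinct error instead of silently returning an
empty list. Multi-model PDB is the trajectory interchange format; writing
rounds coordinates to the format's three decimals, and the round-trip is
exact at that precision.

## Topology defaults and open boundaries

The packaged topology pins every value the source material states:
domains, linker, triad, opening pair, sensor-loop gap, loop-stump
truncations. Secondary-structure element boundaries (hence the precise
loop and hinge intervals) are not enumerated anywhere authoritative, so
the packaged intervals are approximate defaults anchored on residues with
known assignments (A197 in loop LB, P225/V226 in LC, V325/M323/F331 in
the β11-L2-β12 cluster, Y361–E376 in β14-α5, A424/E425/Y428 in α7) and
are user-overridable in the topology file; analyses that depend on them
(hinge contacts) should be read with that tolerance in mind.

## Numerical notes and limitations

Degenerate geometry (collinear superposition sets, < 3 Cα per domain,
unrealizable triad triangles) raises typed errors rather than warnings.
The identity rotation reports angle 0 with the reference direction as its
(arbitrary) axis. Contact ties are broken by atom-name order. The
optimizer's greedy descent can in principle stop at a non-global basin
when the clash term creates near-degenerate minima; across generator
seeds the closed-vs-open disagreement stays within ~1 Å per restraint,
and the annealed mode is available where more exploration is wanted. The
classification's viewer convention reduces a 3D axis position to a sign;
two rotations with the same sign but different axis locations are not
distinguished by the label. PCA assumes the alignment has removed rigid
motion; applying it to unaligned frames mixes rigid and internal modes.
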