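# Methods

This note documents the model implemented by `eemcc`, the choices made
where the formulation leaves room, and what the synthetic fixtures do and
do not establish.

## Unit hierarchy

Atoms are partitioned three ways, and every entropy/enthalpy term is
attached to exactly one level:

* **United atom (UA)** — a heavy atom plus all hydrogens bonded to it.
  The geometry class is decided from topology alone (hydrogen count):
  no hydrogens → *point* (0 rotational modes), one hydrogen → *linear*
  (2 modes), two or more → *nonlinear* (3 modes).  Using topology rather
  than instantaneous geometry keeps the mode count deterministic.
* **Monomer** — a residue of a chain, or a whole small molecule (water,
  ion).  Water monomers are exactly one UA; a violation is an input error.
* **Polymer** — a connected component of the covalent bond graph, i.e. a
  whole molecule.

Monomers are contiguous `(segid, resid)` runs; residue kinds (water, ion,
protein, other) come from a residue-name dialect table.  Hydrogens bonded
to zero or several heavy atoms abort the build with the atom named.

## Vibrational entropy

For a set of N units at one level, the 3N×3N force covariance has
elements `⟨F_a·F_bᵀ⟩/√(M_a M_b)` over net unit forces expressed in local
frames, and the torque covariance stacks `τ/√I` components per unit
(3/2/0 by geometry class).  Eigenvalues λ map to frequencies
ν = √(λ/kBT)/2π; in the package's internal units (kJ mol⁻¹, Å, amu) the
conversion of λ/kBT to s⁻² is exactly 1e26.  Per-mode entropy is the QHO
expression; T ≤ 0 is rejected.

Choices the formulation leaves open, decided here:

* **Removed modes.** At sub-molecule levels the six smallest force
  eigenvalues are dropped (not a rigid-body projection); with fewer than
  seven modes everything is dropped.  Dropped and clamped (λ < 0,
  statistical noise) modes contribute zero entropy and are counted in the
  `ModeSpectrum` bookkeeping — the QHO expression diverges as ν → 0, and a
  removed degree of freedom belongs to the level above.
* **Local frames.** Whole molecules use principal axes of inertia at the
  centre of mass.  Residues use the backbone frame (origin at the N/CA/C
  mean, x along N→C, y normal to the N–CA–C plane); a collinear backbone
  falls back to principal axes with a warning.  Residue *translations*
  use the parent molecule's principal axes.  UA rotations use the frame
  with z along the mean H-bond vector; the in-plane x axis is anchored to
  the first heavy-atom bond (orthogonalised against z), falling back to
  an H vector and then to a global-axis projection.  This anchoring makes
  every frame co-rotate rigidly with the molecule, which is what the
  frame-invariance test (global rotation of coordinates + forces changes
  no entropy term beyond 1e-8) exercises.  Axis signs follow a
  deterministic rotation-covariant convention (positive projection onto
  molecule-fixed reference vectors, third axis by cross product); sign
  flips are similarity transforms of the covariance and cannot change
  eigenvalues, but a consistent convention avoids mixing conventions
  across frames of a trajectory.  For symmetric rotors with degenerate
  inertia moments the principal-axis choice within the degenerate
  subspace is arbitrary; none of the supported fixtures are degenerate.
* **Inertia weighting.** Moments of inertia are computed per frame about
  the unit origin along the local axes and used to weight that frame's
  torques, rather than time-averaging inertia first.  Near-zero moments
  (below 1e-12 amu Å²) zero the component.
* **Torque matrix for linear units** uses only the two components normal
  to the symmetry axis; the on-axis moment of a heavy-atom + single-H
  unit is numerically zero and carries no physical mode.
* **Waters** are single top-level units (3 translational + 3 rotational
  modes, no 6-mode removal).  Within a grouping class the covariance
  statistics of all member waters are pooled over frames before
  diagonalisation so small classes converge; the entropy is reported per
  molecule.

## Conformational (topographical) entropy

The dihedral inventory is generated from the heavy-atom bond graph: one
dihedral per heavy–heavy central bond, terminal atoms being the
lowest-index heavy neighbours.  This yields φ/ψ-type backbone dihedrals
and side-chain χ chains; inter-residue (ω-type) dihedrals attach to the
later residue; impropers are not generated.  Angles are histogrammed on
12 circular 30° bins; peaks are bins strictly above both circular
neighbours, plateau runs merging to the lowest bin index, and a flat
histogram degenerates to a single peak at the modal bin.  Frames are
labelled by nearest peak (circular distance, ties to the lower angle).
The residue entropy is the plug-in Shannon entropy of the joint label
tuples; no sparse-state bias correction is applied.

## Water orientational entropy

Classes c are the waters' nearest-solute labels (bulk, or the identity of
the nearest residue), with weights p_c the fraction of water-frames in
each class.  Neighbour types n distinguish first-shell water, outer
water, protein UAs and ions.  Donate/accept counts are accumulated over
all frames of a class and only then converted to probabilities (the
defining equations are written on mean quantities).  The logarithm is
evaluated as `ln(N_eff · π^{3/2} · p_HB^av / σ)`; this exponent placement
is pinned down by self-consistency — a homogeneous shell at the bulk RAD
coordination number 5.2 with ideal p_HB = 0.25 must give the bulk-water
value ≈ 10.7 J K⁻¹ mol⁻¹, and `kB ln(5.2·π^{3/2}/8) = 10.69` does.
Arguments ≤ 1 contribute zero (one available orientation has no
entropy) and are logged.

## Shells, hydrogen bonds, grouping

RAD shells are computed at UA centres (heavy-atom positions) with
minimum-image distances in orthorhombic boxes.  The blocking test runs
over *all* closer candidates (not only already-accepted ones); an
`accepted`-only variant is exposed and compared on fixtures, where the
two agree.  An 8 Å candidate pre-filter bounds the O(n·k) search; it is a
performance device only and tests verify it does not alter shells on the
fixtures.  Coincident UA positions raise.

Hydrogen bonds: every hydrogen with positive partial charge considers all
negatively charged atoms inside its UA's shell and takes the most
negative `q_D q_A / r²`; ties break to the lowest acceptor atom index.
Proximity grouping labels each water by the nearest non-water UA in its
shell (ties to the lowest monomer id); waters with no such UA are bulk.
Waters contacting two or more residues emit all unordered residue pairs.

## Enthalpy and free energy

Per-atom potential energies are consumed as dumped by the engine (each
interaction term split equally over its participants); kinetic energies
likewise, with no constraint correction.  Group enthalpy is the sum of
mean per-atom energies, exactly additive under regrouping — asserted to
1e-12 relative in tests.  The PV term is off by default and available via
a toggle (at ambient pressure it is of order J/mol per molecule).
`G = H − T·S` converts entropies from J K⁻¹ mol⁻¹ internally.

## Synthetic fixtures: what they establish

The generators provide exact ground truth: the harmonic sampler draws
positions from the true Boltzmann distribution with forces −kx, so the
covariance pipeline must recover the analytic QHO entropy (2% at 10⁵
samples, limited only by Monte-Carlo error); the water box is a jittered
cubic lattice at liquid density (0.0334 Å⁻³) with rigid 0.9572 Å /
104.52° geometry and TIP3P charges; the dipeptide is built from an
internal-coordinate template so backbone dihedrals are set exactly, with
conformer states drawn from a planted distribution (σ = 10° wrapped
normal about each mode).

What they do not establish: the lattice box is more ordered than liquid
water (its donate/accept statistics are near-ideal and its coordination
number is lattice-like), the dipeptide's forces are white noise rather
than force-field forces, and no fixture has the slow collective modes of
a solvated protein.  Passing tests therefore validate the estimators and
bookkeeping against exact references, not the convergence behaviour on
real trajectories, which requires engine-generated input (coordinates +
forces + per-atom energies, ~5000 frames at 10 ps spacing being a
practical protocol for converged entropies).

## Problem sizes used in tests

Desk-scale throughout, chosen as the smallest sizes at which the analytic
recoveries are comfortably inside their tolerances: 10⁵ samples for the
harmonic pipeline, 10⁴ frames for conformer-entropy recovery, 216 waters
for shell statistics, ≤ 10 particles for exhaustive RAD enumeration, and
a ~50-water solvated dipeptide for the end-to-end pipeline.

## Known limitations

* Orthorhombic boxes only; triclinic minimum image is not implemented.
* Protein orientational entropy, residue-level topographical entropy,
  inter-residue conformer correlations and ion mixing entropy are outside
  the model as implemented; waters beyond the first solute shell are
  treated as bulk.
* The plug-in conformer entropy is biased low for undersampled states.
* Class pooling assumes waters in one class are statistically
  equivalent; strongly heterogeneous classes blur their spectra.
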