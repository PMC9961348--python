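# Methods

`carrierdyn` re-implements, as a reusable desk-scale pipeline, the suite of
structural-dynamics analyses commonly applied to MD trajectories of
mitochondrial carriers (SLC25 family): interaction persistence statistics,
helix bending geometry, RMSD-based clustering with representative-frame
extraction, interhelix contact maps, and helix-group superposition between
the cytoplasm-open (c-) and matrix-open (m-) conformational states.  Every
stage is verifiable without external data through a synthetic-trajectory
generator that plants the features the analyses must recover.

## Data model and trajectory dialect

Trajectories are multi-model PDB files: one `MODEL`/`ENDMDL` block per
frame, identical atom lists across frames, coordinates in Å.  This keeps
every fixture a small text file and the whole pipeline dependency-free at
its core; binary formats (DCD/XTC) are supported by converting to the
internal `Trajectory` (topology + per-frame coordinate arrays) through any
external reader — `Trajectory` accepts a `Structure` and a list of
`(n_atoms, 3)` arrays from whatever source.

Author residue numbering is preserved verbatim and never renumbered.  The
carrier literature numbers residues from the unprocessed sequence (the
initiator methionine counts even though it is removed post-translationally),
so all helix definitions, selections and reports use that numbering.
Alternate locations keep the first conformer; insertion codes are rejected
(none of the structures this pipeline targets use them); files whose models
disagree in atom content fail loudly, naming the model.

The default transmembrane helix ranges for the carnitine/acylcarnitine
carrier are H1 10–40, H2 76–100, H3 110–144, H4 172–197, H5 209–239,
H6 269–297, with the cytoplasmic-half and matrix-half residue selections
used for gate-focused clustering carried in the same `AnalysisConfig`.

## Interaction detectors

All detectors operate on heavy atoms, so crystal structures without
hydrogens work throughout.

**Salt bridges.** For every (acidic, basic) residue pair — Asp OD1/OD2,
Glu OE1/OE2 versus Lys NZ, Arg NE/NH1/NH2 — the bridge is present in a
frame iff the minimum O–N distance is ≤ 4.0 Å, with no angle criterion.
Histidine (ND1/NE2) participates only when explicitly enabled, since its
charge state depends on an upstream protonation assignment the pipeline
does not perform.

**Hydrogen bonds.** Present iff the donor–acceptor heavy-atom distance is
≤ 3.0 Å and the donor–H–acceptor angle is ≥ 135°.  When the topology has
no hydrogens the angle criterion is waived and the reported angle is
undefined (NaN); this is the crystal-structure fallback.

**Hydrophobic contacts.** Minimum distance between apolar side-chain heavy
atoms (C and S of Ala/Val/Leu/Ile/Pro/Phe/Trp/Met/Cys and the Tyr ring
carbons) ≤ 4.5 Å.  4.5 Å is the conventional heavy-atom contact criterion;
some native-contact tools default to looser cutoffs (7 Å), so the value is
a config field and reported counts are only comparable at matched cutoffs.

**Cation-π.** Distance from the aromatic ring centroid to the cationic
nitrogen (Lys NZ, Arg guanidinium, or a ligand trimethylammonium nitrogen),
and the elevation angle of the centroid→cation vector over the ring plane:
90° means the cation sits on the ring normal, 0° in-plane.  Presence is
distance-only (≤ 6.0 Å); the angle is monitored, not thresholded, because
the stacking geometry is a property worth reporting rather than gating on.
For Trp the six-membered ring is used by default (five-ring and full-indole
centroids are selectable); for Arg the guanidinium plane plays the role of
the "ring".  The cation position is a single well-defined nitrogen rather
than a methyl-carbon centroid; at the 4.4–4.9 Å distances these analyses
report, the two conventions differ by less than the frame-to-frame spread.

**Persistence.** A trajectory-level series records per-frame presence,
distance and angle; the persistence (occupancy) is the fraction of frames
present, and averages are taken over present frames only.  Reports keep
interactions whose persistence is *strictly greater than* 10% of the
frames, sorted by persistence — the convention of occupancy tables in the
carrier MD literature ("higher than 10%" is read as strict).

Trajectory-level scans are vectorized (one distance matrix per frame,
reduced blockwise to per-residue-pair minima) and are verified in the test
suite against a brute-force double loop over qualifying atom pairs.

## Helix geometry

Local helix axes use the bisector construction over sliding windows of four
consecutive Cα atoms (the HELANAL lineage): with window points P1..P4, the
bisectors V1 = (P1−P2)+(P3−P2) and V2 = (P2−P3)+(P4−P3) point toward the
local axis, and unit(V1×V2), sign-canonicalized to run N→C, is the window
axis.  A helix of n residues yields n−3 axes.  Straight (untwisted) chains
make the cross product vanish and are rejected as degenerate.

The bend between consecutive window axes localizes a kink: the kink is
reported as the residue boundary (i, i+1) under the maximum local bend,
ties breaking toward the N-terminus.  The single per-helix bending angle is
the angle between the mean axis of the first third of windows and the mean
axis of the last third.  This aggregation is deliberately insensitive to
single-window noise (a max over window pairs is not) and reduces exactly to
the planted angle for a two-segment kinked helix; it is the package's
definition, documented so numbers are comparable across runs.

Per-frame profiles are averaged arithmetically over frames.  Arithmetic
averaging of angles is adequate in the sub-90° regime TM helix bends occupy;
no circular statistics are needed there.  Angles are computed with
atan2(|u×v|, u·v), which stays accurate near 0° where arccos of a dot
product loses six digits.

## Clustering

Frame-to-frame distances are Kabsch-superposed Cα RMSDs on a configurable
selection (default: the six TM helix ranges), each pair fitted
independently.  The fast path evaluates the fitted RMSD from the singular
values of the paired covariance; for exactly rigid pairs this cancels to
~1e-7 Å rather than exact zero, far below any decision threshold the
pipeline uses.  A `drop_first` parameter discards pre-equilibration frames;
the default is 0 because no universal frame count exists — it is a judgment
call made per trajectory.

Clustering is the gromos scheme: repeatedly take the unassigned frame with
the most unassigned neighbours within the RMSD cutoff, make it a centroid,
remove it and its neighbours as a cluster.  Ties on neighbour count break
toward the lowest frame index, making the procedure fully deterministic.
The representative conformation is the centroid of the most populated
cluster (size ties: the earlier-extracted cluster).  Cutoff choice is a
compromise between total cluster count and singleton count; a `cutoff_scan`
reports both across a grid instead of automating the judgment.

## Two-state comparison

Conformational asymmetry is quantified by superposing chosen helix groups
independently: for each group (e.g. H3-H4-H5 and H6-H1-H2), the paired Cα
atoms restricted to the group's ranges are Kabsch-fitted and the all-pair
RMSD plus per-residue deviations are reported.  No iterative pair pruning
is applied by default — pruning hides exactly the repacking signal this
analysis exists to measure — though the per-residue deviations let a user
apply any pruning rule downstream.  Same-protein state pairs are matched by
identical author numbering; cross-homolog pairs are matched through a
global Needleman–Wunsch alignment (BLOSUM62, gap open 10, extend 1 —
conventional global-alignment defaults).

A point worth spelling out: a helix group that moves as one rigid body
between states is *invisible* to this measure, because the group fit
absorbs any common rigid transform.  What the group RMSD reports is the
change in the group's internal geometry — helices repacking relative to one
another.  This is also why the per-group RMSD can never exceed the RMSD of
the same residues under a single whole-protein fit.

Contact asymmetry subtracts interhelix heavy-atom contact counts (same
helix definitions, same cutoff) between states, reporting per-interface
deltas sorted by magnitude.  Absolute counts depend on the contact
definition and cutoff; orderings and signs of deltas are the robust
surface.

## Synthetic data generator

The generator emulates the geometry the analyses key on, not the physics:

- **Bundle.** Six ideal α-helices (rise 1.5 Å/residue, twist 100°/residue,
  Cα radius 2.3 Å), antiparallel, placed on a circle of radius 8.0 Å —
  chosen so flanking helices touch at contact range, as TM helices do.
  Each residue carries a Cα and an outward CB pseudo-atom; helix k spans
  residues (k−1)·30+1 .. k·30 of chain A.
- **Planted interactions.** Minimal pseudo-residues with correct PDB atom
  names (ASP OD1/OD2 + LYS NZ; TYR OH/HH + GLU OE1; LEU CD1 pairs; a PHE
  ring hexagon + a cationic NZ).  Per frame each interaction independently
  samples bound/unbound at its occupancy; bound geometry realizes the
  planted distance/angle exactly, unbound teleports beyond the detection
  cutoff with a ≥3σ margin.  H-bond geometry places the hydrogen by the
  law of sines so the donor–H–acceptor angle is exact.  Occupancy is iid
  Bernoulli by default; an exact-count mode (round(p·n) bound frames at
  shuffled positions) exists for boundary checks where the empirical
  fraction must hit the nominal occupancy exactly — an iid draw straddles
  a threshold placed exactly at p with probability ~1/2 at any n.
- **Jitter.** Isotropic Gaussian noise on every atom, every frame
  (default σ 0.05 Å for interaction fixtures, 0.1 Å for state fixtures).
- **Two states.** State B displaces each moved helix along its *own*
  radial direction by the planted magnitude, signs alternating between
  consecutive moved helices.  The alternation gives the displacement field
  zero net translation and zero net torque, so the group superposition
  cannot absorb it and the group RMSD reads back the planted magnitude
  (≈1.8 Å planted → 1.80–1.83 Å measured at σ=0.1).  A single common
  rigid displacement of the whole group would, by the argument above, be
  removed by the fit and recover nothing.
- **Determinism.** One `numpy` Generator per trajectory, seeded from the
  spec; identical spec + seed gives bit-identical coordinates.  Every
  fixture ships a ground-truth sidecar (per-frame bound/unbound records,
  planted parameters, displacement magnitudes).

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: force-field dynamics and kinetics
(bound/unbound switching is teleportation), correlated motions, side-chain
rotamers beyond the minimal pseudo-atoms, membrane and solvent, and the
broken symmetry of real carrier folds.  The tests establish that the
*measurements* are correct on geometry where the answer is known; applying
them to real trajectories inherits all the usual caveats of the underlying
conventions (cutoff choices, helix definitions, equilibration trimming).

## Numerical choices

- Kabsch superposition: SVD of the paired covariance with reflection
  correction; fewer than 3 pairs or collinear point sets raise, since the
  rotation is under-determined.
- RMSF: frames are fitted to the running mean structure, iterating until
  the mean moves < 1e-10 Å (capped at ten passes; rigid-plus-jitter data
  converges by pass three), which makes the result rigid-motion independent
  to ~1e-10 Å.  An optional fit selection allows fitting on a rigid core
  while measuring a flexible region.
- Ring normals: eigenvector of the smallest covariance eigenvalue,
  canonicalized to positive z (positive x if z vanishes).
- Report precision: CSV tables print distances/angles/fractions at two
  decimals, matching the precision at which occupancy tables are usually
  published; JSON reports keep full precision.

## Problem sizes

Fixtures use 30-residue helices, six-helix bundles (360 atoms), 100–500
frame trajectories, and 50-frame distance matrices — sizes at which every
stage cross-checks against brute-force references in seconds while
exercising the same code paths a 2 μs production trajectory would.

## Known limitations

- Absolute interhelix contact counts are calibration-dependent (atom set,
  cutoff); only orderings/deltas transfer across tools.
- The single per-helix bending angle depends on the chosen aggregation;
  other tools aggregate differently, so compare profiles, not scalars.
- Cross-homolog superposition requires user-supplied helix ranges for the
  second protein; none are inferred.
- PDB parsing is deliberately minimal (no mmCIF, no insertion codes, first
  altloc only); convert richer inputs upstream.
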