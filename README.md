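# carrierdyn

Structural-dynamics analysis of mitochondrial carrier (SLC25-family)
transporters from MD trajectories and structural models: interaction
persistence statistics, transmembrane-helix bending geometry, RMSD-based
clustering, interhelix contact maps, and helix-group superposition between
the cytoplasm-open (c-) and matrix-open (m-) conformational states.

Carriers such as the carnitine/acylcarnitine transporter SLC25A20 work by
alternating access: a six-TM-helix bundle (H1–H6, three pseudo-symmetric
domains) switches between a c-state and an m-state, each closed on one side
by a network of salt bridges.  The questions this package answers from a
trajectory or a pair of state models are the ones that characterize that
cycle:

- **Which interactions hold the states together, and how persistently?**
  For each residue pair and interaction class (salt bridge, hydrogen bond,
  hydrophobic contact, cation-π) the pipeline reports the *persistence*
  (fraction of frames the geometric criterion holds, e.g. min O–N distance
  ≤ 4 Å for a salt bridge) and the average distance/angle over present
  frames, keeping interactions with persistence > 10%.
- **How do the helices bend?**  Local helix axes from sliding four-Cα
  windows (the HELANAL construction) give per-window bend angles, a
  per-helix bending angle, and the residue boundary of the kink.
- **Which conformations dominate?**  Gromos clustering on the pairwise
  Cα-RMSD matrix extracts representative frames (cluster centroids).
- **Where is the conformational change?**  Superposing helix groups
  independently (e.g. H3-H4-H5 vs H6-H1-H2) turns the asymmetry of the
  c↔m transition into per-group RMSDs and per-residue deviations, and
  contact-map differencing localizes it to helix interfaces.

A synthetic-trajectory generator (`carrierdyn.synthgen`) builds six-helix
bundles with planted interactions (known occupancy and geometry), planted
kinks, Gaussian jitter, and two-state pairs with a known displaced helix
subset — so every stage of the pipeline is verified against exact ground
truth without downloading any data.

## Worked example

Generate a 500-frame synthetic trajectory with a salt bridge planted at
60% occupancy and 2.9 Å bound distance (plus a 5% decoy), then measure it:

```sh
carrierdyn simulate --preset salt-bridge --n-frames 500 --seed 42 --out demo/sim
carrierdyn interactions --traj demo/sim/fixture.pdb \
    --config demo/sim/bundle_config.yaml --out demo/out
```

`demo/out/interactions.csv` contains (salt-bridge row shown):

```
Residue1 Residue2        Kind  Fraction  AvgDistance  AvgAngle
    Asp8    Lys52 salt_bridge      0.60         2.90
```

The measured persistence 0.60 is the empirical occupancy of the planted
bridge (the sidecar `ground_truth.json` lists the exact per-frame states;
detector and sidecar agree frame for frame), and 2.90 Å is the planted
bound distance recovered through 0.05 Å coordinate jitter.  The 5% decoy
is absent from the table — the strict >10% persistence filter removed it.

Two-state asymmetry — helices 6, 1, 2 displaced by 1.8 Å, jitter 0.1 Å:

```sh
carrierdyn simulate --preset two-state --n-frames 3 --seed 42 --out demo/two
carrierdyn compare-states --traj demo/two/state_a.pdb --state-b demo/two/state_b.pdb \
    --config demo/two/bundle_config.yaml --out demo/cmp
```

prints

```
H3-H4-H5: RMSD 0.25 Å over 90 Cα
H6-H1-H2: RMSD 1.82 Å over 90 Cα
```

The undisturbed group superposes to jitter level (0.25 Å) while the group
containing the moved helices reads back the planted 1.8 Å repacking — the
signature of an asymmetric conformational transition, localized to the
right helices.  `demo/cmp/comparison.json` adds per-residue deviations and
per-interface contact deltas.

The other commands follow the same pattern: `helix-geometry` (bending/kink
CSV), `cluster` (RMSD matrix, gromos clusters, representative frame),
`contact-map` (interhelix contact counts).  Every run writes a
`manifest.json` snapshot sufficient to reproduce it; reports are
byte-identical across re-runs.

Real data plug in the same way: any multi-model PDB works as `--traj`, and
a YAML config carries the helix ranges and cutoffs (defaults are the
SLC25A20 TM helix ranges in author numbering, salt bridge 4.0 Å, H-bond
3.0 Å/135°, hydrophobic 4.5 Å, cation-π 6.0 Å, persistence 10%).

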