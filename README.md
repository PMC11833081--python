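# loopscape

Post-processing toolkit for multi-frame structural ensembles of two-chain
protein complexes, built around the conformational regulation of
**cathepsin B (CTSB)** by its **occluding loop**: a surface loop (residues
185–200, UniProt numbering) that can cover the active site (residues 108,
278, 298) and switch the enzyme between an auto-inhibited *closed* state
and a proteolytically active *open* state.  Ligands such as domain-swapped
cystatin C dimers can bind an allosteric pocket on the enzyme's rear side
and shift this equilibrium — the effect this toolkit is designed to
quantify from molecular-dynamics ensembles.

It is aimed at structural bioinformaticians who have an MD ensemble (e.g.
from replica-exchange sampling) as a multi-model PDB file and want to
answer: *how often is the loop open, where does the ligand bind, and does
binding open the loop?*

## What it computes

1. **Open/closed states.** The reaction coordinate is the centre-of-mass
   distance between two atom groups,
   `d = ‖COM(loop) − COM(active site)‖`, with mass-weighted centroids over
   heavy atoms (standard atomic weights).  A frame is *closed* when
   `d ≤ 16.5 Å` (boundary inclusive) and *open* otherwise; a threshold
   scan reports the empirical CDF of `d` over a grid.  The activation
   effect of a perturbation is summarised as the fold change
   `mean(f_open, case) / mean(f_open, reference)`.
2. **Inter-chain contacts.** Two heavy atoms of different chains are in
   contact when their distance is strictly below 3.3 Å (0.33 nm).
   Ensembles are filtered by *any* inter-chain contact, or by contacts to
   a named site (e.g. the allosteric-pocket residues 169, 215, 221, 222,
   224, 333).  Per-residue statistics are frame-normalised contact counts
   (a value > 1 means a residue touches several partners at once) and are
   exportable as an edge-list contact network.
3. **Contact-contact PCA (ccPCA).** An equal-size heavy-atom mesh is built
   across the two chains (all *m* atoms of the smaller chain; every
   ⌊n/m⌋-th atom of the larger), the per-frame distances of all m×m mesh
   pairs form the feature matrix, and PCA projects frames onto PC1/PC2.
   The 2D score histogram is Boltzmann-inverted into a Gibbs free-energy
   landscape, ΔG = −RT·ln(P/max P) (R in kJ/(mol·K), T = 300 K by
   default), and the scores are clustered with OPTICS to isolate binding
   configurations, each with a representative frame and per-cluster loop
   statistics.
4. **Group statistics.** One-way ANOVA across named distance groups with
   Dunn–Šidák-corrected pairwise comparisons, `p_adj = 1 − (1 − p)^m`.
5. **Synthetic benchmark ensembles.** A seeded generator produces
   two-chain ensembles with known open fractions, binding poses and
   contact patterns (plus ground-truth tables), so every stage can be
   validated without any external trajectory.

## Worked example

Run the full pipeline on a synthetic binding ensemble in which 70% of
frames have the ligand docked in the allosteric pocket (with loop opening
probability 0.72) and 30% have it detached (opening probability 0.2):

```sh
cat > demo.yaml <<EOF
mode: binding
synthetic:
  n_frames: 1000
  n_poses: 2
  pose_occupancies: [0.7, 0.3]
  pose_open_fractions: [0.72, 0.2]
seed: 7
EOF
loopscape run --config demo.yaml --out demo_run --seed 7
```

prints

```
loopscape run report (v0.1.0)
...
n_frames_input	1000
n_frames_post_filter	703
n_frames_clustered	703
fraction_open	0.553000
n_clusters	2
fraction_open_bound	0.718350
fraction_open_unbound	0.161616
fold_change_open	4.444790
```

Reading: of 1000 frames, 703 passed the contact filter (exactly the
pocket-bound frames), and OPTICS resolved the bound ensemble into two
conformational clusters.  `demo_run/cluster_summary.tsv` shows they are
the open and closed loop states of the bound enzyme:

```
cluster	n_members	mean_distance_angstrom	sd_distance_angstrom	open_fraction
0	505	20.026367	0.774651	1.000000
1	198	11.970787	0.887173	0.000000
```

The open fraction is 0.718 among pocket-bound frames versus 0.162 among
unbound ones — a 4.4-fold activation by binding, recovering the planted
allosteric coupling.  `demo_run/` also contains the per-frame state table,
PC scores, the ΔG landscape grid and one representative PDB model per
cluster.

The same analyses are available as library functions
(`loopscape.classify_states`, `loopscape.detect_contacts`,
`loopscape.fit_pca`, …) and as individual subcommands (`loopscape states`,
`scan`, `contacts`, `filter`, `ccpca`, `compare`, `simulate`).

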