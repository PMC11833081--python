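# Methods

This note documents the models, conventions and numerical choices behind
loopscape, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Occluding-loop state model

The conformational state of cathepsin B's occluding loop is reduced to a
single reaction coordinate: the Euclidean distance between the
mass-weighted centroids of the loop group (residues 185–200) and the
active-site group (residues 108, 278, 298), both in UniProt numbering and
taken verbatim from the input file (no renumbering).  Frames with
`d ≤ threshold` are *closed*, frames with `d > threshold` are *open*; the
boundary is deliberately inclusive on the closed side.  The default
threshold is 16.5 Å, shipped in the `ctsb-murine` preset and fully
configurable; a threshold scan (default grid 12–24 Å in 0.1 Å steps)
exposes the full empirical CDF so the choice can be inspected rather than
trusted.

**Centre-of-mass convention.**  COM is computed over heavy atoms with
standard atomic weights.  MD engines that repartition hydrogen masses
would give slightly different all-atom COMs; restricting to heavy atoms
with standard weights makes the coordinate independent of the generating
engine.  Selections can include hydrogens (`heavy_only=False`) for
sensitivity checks.

**Fold change.**  The activation statistic is the ratio of group means,
`mean(f_open over case conditions) / mean(f_open over reference
conditions)` — not a mean of pairwise ratios.  The ratio-of-means form is
stable when individual reference fractions are small and makes the
statistic symmetric in how replicate simulations are pooled.

## Contacts

A contact is two heavy atoms of *different* chains at distance strictly
less than 3.3 Å; a pair at exactly 3.3 Å is not a contact.  One convention
is applied pipeline-wide (detection, filtering, statistics, mesh
construction): hydrogens never participate.

Per-residue statistics count **residue pairs**, not atom pairs: a residue
touching two partner residues in one frame contributes 2, so
frame-normalised values above 1 mean multivalent binding.  Per-pair values
are fractions of frames and lie in [0, 1].

Two kernels compute the same contact set: an exhaustive all-pairs kernel
(used below 500×500 atom pairs, and kept as the correctness oracle in the
tests) and a k-d tree spatial query for larger systems.  The tree kernel
is scipy's `cKDTree` sparse distance query with the strict inequality
re-applied; equivalence of the two kernels on random frames is asserted in
the test suite, pair-for-pair.

Frame filters (any-contact; site-contact against a residue set such as the
allosteric pocket {169, 215, 221, 222, 224, 333}) compose by logical AND.
Filtering is idempotent: re-filtering a filtered ensemble keeps all
frames.

## Contact-contact PCA

The mesh rule makes the two chains contribute equally: the smaller chain
provides all *m* heavy atoms in (residue number, atom name) order; the
larger chain is strided by k = ⌊n/m⌋ (first *m* strided atoms kept).  The
feature vector of a frame is the distance of every mesh pair — the full
m×m cross product by default, because it is the most literal notion of
"all pairs between the meshes".  For very large systems m² can exceed
memory, so a seeded uniform subsample (`cap`) is available; it is off by
default and recorded in the mesh metadata, and identical topology + seed +
cap reproduce the pair list exactly.

PCA is computed by SVD of the column-centred feature matrix.  No scaling
is applied (all features are distances in Å); zero-variance columns are
dropped before the fit and recorded, reappearing as zero loadings.  The
sign of each component is fixed so its largest-magnitude loading is
positive, making scores reproducible across linear-algebra backends.  The
full spectrum is retained on the model so the variance budget
(Σ explained = total variance) and the full-rank reconstruction are
testable properties rather than assumptions.

## Free-energy landscape

The PC1/PC2 scores are histogrammed (default 100×100 bins over the
observed range per axis plus 1% padding; 0.5 Å fallback padding for a
degenerate axis) and Boltzmann-inverted:

    ΔG = −RT · ln(P / max P),   R = 0.008314462618 kJ/(mol·K), T = 300 K.

T defaults to 300 K, the physically meaningful bottom of a
replica-exchange temperature ladder, and is configurable.  The modal bin
has ΔG = 0 exactly (implemented as RT·ln(maxP/P) so the minimum is +0.0);
empty bins are *masked* (NaN + mask array), not assigned an infinite or
sentinel energy, so downstream consumers never see non-finite values
unmasked.  The transform is exactly invertible on occupied bins —
renormalising exp(−ΔG/RT) reproduces P to machine precision — and that
round trip is asserted in the tests.

## OPTICS clustering

Scores are clustered with scikit-learn's OPTICS using xi extraction.
Defaults: `min_samples = max(20, 2.5% of frames)`, `xi = 0.15`.  These
were chosen by measuring extraction behaviour on known-structure score
sets: with small `min_samples` (~10) or small `xi` (~0.05) the xi
procedure reports spurious leaf clusters inside a single density mode and
demotes large smooth clusters to noise — observable already on two clean,
well-separated Gaussian blobs — while the chosen defaults recover one
cluster per planted density mode with zero noise across seeds, for K ∈
{1, 2, 3} planted modes.  Both parameters are exposed on the API, the CLI
and the run config, and are echoed into output metadata.

Clusters are relabelled in descending size (ties by extraction order);
noise keeps label −1.  Each cluster's representative is the member frame
nearest the member centroid in score space (ties: lowest frame position),
and per-cluster summaries report mean ± SD (sample SD, ddof = 1; 0 for
singletons) of the loop COM distance and the open fraction at the state
threshold.

Note that ccPCA features span whole chains, so *every* collective degree
of freedom large enough to move mesh distances shows up in score space.
In particular, free occluding-loop dynamics add a loop-state axis: a
two-pose ensemble with an unconstrained loop genuinely contains 2×2
density modes (pose × loop state), and OPTICS correctly reports four
clusters.  Benchmarks that target pose recovery therefore hold the loop in
one state; this is a property of the method, not an artefact.

## Group comparison

One-way ANOVA is computed from the explicit sums of squares; degenerate
inputs with zero between- and within-group variance return F = 0, p = 1
(identical constant groups carry no evidence).  Pairwise comparisons are
two-sided t tests on the pooled within-group variance with N − G degrees
of freedom (classical post-hoc convention); a Welch variant is available
behind a flag.  Multiplicity is corrected with Dunn–Šidák,
`p_adj = 1 − (1 − p)^m` over all m = G(G−1)/2 pairs, clamped to [0, 1];
the adjustment is monotone and the identity at m = 1.

**Caveat:** consecutive MD frames are autocorrelated, so frame-level
p-values are anti-conservative.  The module computes the classical
statistics exactly as defined and applies no effective-sample-size
correction; prefer per-simulation means as the unit of analysis when
replicate simulations exist (both units are accessible through the API).

## Synthetic ensembles

The generator emulates the *statistical* structure the analysis assumes —
it makes no claim to stereochemical realism.  Residues are rigid clusters
of four heavy atoms (C/N/O, standard masses) on a schematic template; the
enzyme chain (E) carries residue numbers matching the `ctsb-murine` preset
groups so preset-driven analyses run unchanged on synthetic data.

* **Loop states:** per frame, open/closed is Bernoulli(f_open) and the
  loop group is rigidly translated along a fixed axis so its heavy-atom
  COM sits exactly at `d_state + N(0, σ)` from the active-site COM — the
  noise lives on the COM coordinate itself, so the planted σ is the σ of
  the measured distance.  Defaults: f_open = 0.25, d_closed = 12 Å,
  d_open = 20 Å, σ = 0.8 Å, 2000 frames — a closed-dominant enzyme
  (~75% closed) with well-separated states (10σ).
* **Binding poses:** a ligand chain (I) of 15 schematic residues is placed
  per frame at one of K pose offsets (default spacing 10 Å) plus
  component-wise Gaussian jitter clipped at 3σ (σ = 0.5 Å).  Poses flagged
  as pocket-binding are pulled along the closest ligand→pocket atom axis
  until that atom pair sits at 2.9 Å, guaranteeing a contact under the
  3.3 Å cutoff; all other poses are placed so that, even at maximal
  clipped jitter, no ligand atom comes within 3.3 Å of any enzyme atom.
  Contact-based filters therefore have exact ground truth.
* **Allosteric coupling:** `pose_open_fractions` makes the loop-state
  probability follow the pose, emulating binding-induced opening.
* **Determinism:** all draws come from one `numpy` Generator seeded from
  the spec, in a fixed order; identical spec + seed reproduce the
  ensemble, the ground-truth table and every downstream output
  byte-for-byte.

What passing tests on this generator do **not** show: robustness to real
protein features — internal side-chain flexibility, partial/ambiguous
contacts at the cutoff boundary, anisotropic loop motion, overlapping pose
basins, or force-field artefacts.  They establish that each stage computes
its defined quantity correctly and that the composed pipeline recovers
planted parameters at the expected statistical precision.

## Problem sizes

Tests and the acceptance script use desk-scale ensembles chosen so the
statistical bounds are meaningful: 2000 frames for state recovery (3σ
binomial bound 0.029 on f = 0.25), 1000 frames for two-pose recovery,
1200 for three poses, 50 random 500-atom frames for kernel equivalence,
and 2000 replicates for the ANOVA null calibration.  The full suite runs
in well under a minute of compute on one CPU.

## Known limitations

* Multi-model PDB is the only required trajectory format; insertion codes
  are rejected and only primary altLocs are kept (trajectories should not
  contain either).  Binary formats can be converted externally.
* No kinetic or time-lagged analysis: replica-exchange ensembles are not
  time-ordered, so only equilibrium populations are meaningful.
* No reweighting across replica temperatures; the landscape temperature
  only scales ΔG.
* Frame-level significance tests inherit the autocorrelation caveat above.
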