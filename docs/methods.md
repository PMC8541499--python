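# Methods

This note documents the models and procedures implemented in `confens`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical choices that affect results.

## Ensemble representation

A `ConformationalEnsemble` is an (frames × atoms × 3) float64 array in
nanometres plus a topology (atom names, elements, masses, 0-based residue
ordinals, residue names, chains) and a per-frame replicate label. All
internal lengths are nm; PDB I/O converts from/to Ångström, so a write →
read round trip is exact only to the PDB coordinate precision (10⁻⁴ nm).
Phosphorylated residues are recognised by the PDB chemical-component codes
SEP, TPO and PTR plus a user-extensible alias list, and carried on the
topology as a set of residue indices. Missing masses are filled from a
standard atomic-weight table keyed on the element, falling back to the
first character of the atom name. Hydrogens are kept when present — the
hydrogen-bond criterion needs them — and each analysis states whether it
uses heavy atoms only (contact maps do, by default).

## Global dimensions

*R*g is the mass-weighted root-mean-square distance from the centre of
mass over all selected atoms, the convention of common MD analysis tools.
*R*ee defaults to the CA atoms of the first and last residues (the bead
atom for single-bead polymer models); the endpoint atom is configurable
because different conventions exist and the terminal heavy atoms are not
always saved.

The shape factor is defined here as

    rs = <Ree^2> / <Rg^2>   ("mean-square" convention).

The ratio of averages can also be formed as `<Ree>^2 / <Rg>^2`
("square-of-mean"), and both modes are exposed; mean-square is the default
because only that convention makes the ideal-chain and rod references
exact: a freely-jointed chain of N bonds has ⟨Ree²⟩ = N b² and
⟨Rg²⟩ = b² N(N+2)/(6(N+1)), hence rs = 6(N+1)/(N+2) → 6, and the discrete
rod has rs = 12N/(N+2) → 12. The error on rs is first-order propagation of
the two block errors.

### Block averaging

Frames from a trajectory are autocorrelated, so the naive standard error
of a time average is biased low. The Flyvbjerg–Petersen transform is
applied: the series is repeatedly pair-averaged; at each level the naive
standard error sqrt(var/n_blocks) is recorded with its own statistical
uncertainty err/sqrt(2(n_blocks−1)). The reported error is the plateau of
this curve: the first level whose increase to the next level is inside its
uncertainty band marks the plateau onset, and the error estimates from
there up to the last level with ≥ 16 blocks are averaged (averaging tames
the large fluctuations of high blocking levels). If the curve is still
rising at the last usable level the maximum is returned and the result is
flagged unconverged; series shorter than 32 frames trigger a warning and
fall back to the naive i.i.d. error. Calibration: on i.i.d. normal series
of 2¹⁴ points the estimate is within 20% of 1/√n, and on AR(1) series with
φ = 0.9 and 2¹⁶ points within 25% of σ√((1+φ)/(1−φ))/√n.

### Distributions

Densities of scalar observables use a Gaussian KDE with Scott's bandwidth
(n^(−1/5) × sample standard deviation), overridable, evaluated on a grid
spanning the data range ± 3 bandwidths.

## Secondary structure

The DSSP algorithm is implemented from the Kabsch–Sander hydrogen-bond
energy (distances in Å, partial charges folded into the prefactor
0.084·332 kcal·Å/mol); a bond is assigned below −0.5 kcal/mol. Two
consecutive n→n+4 turns give α-helix H (n→n+3: G, n→n+5: I), the standard
parallel/antiparallel bridge patterns give B/E (laddered bridges are E,
isolated ones B), hydrogen-bonded turns give T, and CA-chain curvature
above 70° over i−2…i+2 gives the bend S. The priority order is
H > E > B > G > I > T > S. Amide hydrogens are taken from the topology
when present, otherwise placed 0.101 nm from N antiparallel to the
preceding carbonyl — the classic DSSP construction. Prolines and
chain-initial residues never donate; the amide directly following a
carbonyl is excluded (it shares that peptide bond). Phosphoserine and
phosphothreonine are ordinary residues for this purpose (side chains are
ignored).

The unit tests require ≥ 95% residue-frame agreement with an independent
DSSP implementation (mdtraj's) over a panel of built geometries; the
residual tolerance absorbs version-specific tie-breaking at helix ends and
ladder edges.

**PPII extension.** Classic DSSP has no code for the polyproline-II helix,
the dominant local structure of many disordered chains, because PPII is
not hydrogen-bond-defined. After DSSP assignment, coil (C) residues whose
(φ, ψ) lie within φ = −75° ± 29°, ψ = +145° ± 29° in runs of at least two
consecutive residues are relabelled P. The window and run length are a
documented, configurable choice (these are commonly used assignment
values); P never overwrites a hydrogen-bond-derived class, so the
extension can only shrink the irregular fraction. Profile grouping:
helix = H+G, strand = E+B, turn = T, bend = S, PPII = P, irregular = C+I
(π-helix is folded into irregular because the helix group is defined as
α + 3₁₀).

## Interactions

**Contacts.** Two residues are in contact in a frame when any pair of
their atoms is closer than 0.4 nm. Heavy atoms only by default, so maps do
not depend on whether the trajectory stored hydrogens. Sequence-adjacent
pairs are reported (bonded neighbours are trivially in contact); the
diagonal is 1 by convention. Delta-maps are the element-wise difference
phosphorylated − non-phosphorylated.

**Salt bridges.** Bridges between basic groups and phosphates are scored
through hydrogen bonding: a donor–H···acceptor triple is bonded when
r_DA < 0.33 nm − 0.00044 nm/deg² · θ², with θ the H–donor–acceptor angle —
the Wernet–Nilsson-type angle-dependent distance criterion. Both constants
are configurable. Donors: Arg NE/NH1/NH2, Lys NZ, and the N-terminal amine
of each chain, which is always reported as its own "NT" row; acceptors:
the phosphate oxygens O1P/O2P/O3P plus the phospho-ester oxygen, and
optionally Asp/Glu carboxylates. A pair's probability is the percentage of
frames with at least one bond between its atoms.

**Cation–π.** An Arg–Tyr pair interacts in a frame when the distances from
the arginine cation reference atom to tyrosine CG *and* to tyrosine CZ are
both ≤ 0.6 nm (inclusive). Arginine has no NZ atom, so the guanidinium
carbon CZ is used as the cation centre by default; NE/NH1/NH2 are
selectable and the choice is recorded in the table metadata.

**Error bars.** All interaction probabilities report the standard error of
the per-replicate probabilities across replicates (NaN with a single
replicate). This treats replicates as the independent unit, which is the
honest choice when frames within a replicate are correlated.

## Free-energy landscapes

1. *Fitting.* The "central structure" is the medoid under backbone RMSD —
   the frame minimising the summed RMSD to all frames. The search is exact
   up to 5000 frames and uses an evenly spaced 5000-frame subsample above
   that (the fit itself always covers every frame). All frames are then
   least-squares superposed onto the medoid (Kabsch, float64).
2. *PCA.* Principal components of the flattened backbone coordinates
   (N, CA, C, O). For a two-variant comparison the basis is fitted on the
   pooled frames of both ensembles with equal weight per frame, so both
   project into the same space and their landscapes are directly
   comparable; fitting on one variant and projecting the other is
   available behind a flag. The SVD solver is forced to the deterministic
   full decomposition so repeated runs are byte-identical.
3. *Surface.* F = −ln(p/p_max) in RT units, with p a 2-D Gaussian KDE
   (Scott bandwidth per axis — exact here because PC projections are
   uncorrelated by construction) on a 200×200 grid spanning the occupied
   range ± 3 bandwidths. The global minimum is exactly 0.
4. *Basins.* Grid cells at or below the level cutoff (default 5 RT) drain
   by steepest descent over the 8-neighbourhood to a local minimum;
   plateau ties break toward the lower flat index, which makes the
   partition deterministic. A basin's population is the fraction of all
   frames whose projection falls in its cells; frames above the cutoff or
   outside the grid stay unassigned, so populations sum to ≤ 1 (and to 1
   within 0.01 when the cutoff exceeds the occupied maximum). Minima are
   classified ≤1/≤2/≤3 RT, and each basin's representative frame is the
   one projecting nearest to its minimum from inside the basin.

Calibration on two-state synthetic ensembles (70/30 mixture of two
well-separated conformers, 10⁴ frames): exactly two basins, populations
within ±0.05 of the generation weights, and an inter-minimum gap within
0.2 RT of ln(7/3) = 0.847 (Boltzmann inversion of the weights).

## Synthetic generators

All generators are pure functions of their arguments including the seed.

- *Freely-jointed chain*: point beads of unit mass, each bond an
  independent uniformly random direction of fixed length (0.38 nm default,
  a typical CA–CA virtual bond). This is the Gaussian-coil stand-in: it is
  the simplest model whose shape-factor limit is exactly 6. It has no
  excluded volume, no persistence and no side chains.
- *Rigid rod*: collinear equally spaced beads; frames differ only by rigid
  rotations/translations.
- *Backbone builder*: N/H/CA/C/O per residue placed by internal-coordinate
  (NeRF) construction at ideal bond lengths and angles (N–CA 0.1458,
  CA–C 0.1525, C–N 0.1329, C=O 0.1229 nm; ω = 180°), with per-residue
  (φ, ψ). Requested dihedrals are recovered from the coordinates to ≪ 0.5°.
  No amide H on prolines or on the first residue (its amine is not part of
  a peptide plane; DSSP places hydrogens itself when absent). A β-sheet
  fixture builds two extended strands, generates the partner by a two-fold
  rotation about the sheet normal, and grid-searches the inter-strand
  offset that maximises the number of Kabsch–Sander hydrogen bonds.
- *Interaction fixtures*: minimal two-residue systems with correctly named
  atoms whose governing distance equals the requested separation exactly
  (salt-bridge donor/H/phosphate-oxygen geometry at a chosen D–H–A angle;
  Arg CZ equidistant from Tyr CG/CZ; a plain two-atom contact pair).
- *Multi-state mixtures*: each frame is a uniformly random rotation of a
  conformer drawn by the given weights plus isotropic Gaussian coordinate
  noise, with replicate labels assigned evenly. Note that nearly symmetric
  conformers (e.g. a straight strand) can split into mirror clusters after
  RMSD fitting, because two alignments are almost degenerate; the test
  conformers are deliberately low-symmetry.

What passing the synthetic suites does *not* show: real IDP ensembles have
excluded volume, solvation, side-chain packing, and correlated slow
dynamics none of which the generators emulate. The suites validate the
*analysis* (estimators, criteria, recovery of known ground truth), not any
force field.

## Scale of the shipped computations

The test suite and the acceptance script are sized for a single CPU:
10⁴-frame bead ensembles for polymer statistics, 10⁴ frames for the main
landscape-recovery run with 1500-frame ensembles for the 10-seed
population sweep, 2¹⁴–2¹⁶-point series for blocking calibration, and a few
hundred frames for full-pipeline determinism checks. These sizes put the
Monte-Carlo error well inside each tolerance while keeping a full run in
minutes.

## Known limitations

- DSSP ladder/bulge handling is simplified (no β-bulges); agreement with
  reference implementations is therefore bounded at the few-percent level
  on sheet edges.
- The hydrogen-bond criterion requires explicit donor hydrogens; donors
  without hydrogens are skipped (an error is raised only when no donor at
  all can be evaluated).
- Basin delimitation depends on the KDE bandwidth: heavily overlapping
  states merge, and populations are grid-quantised at the 1/grid² level.
- The frames text format stores full float precision but is verbose; it is
  meant for small synthetic ensembles, not production trajectories.
- No binary trajectory formats in core; convert to multi-model PDB first.
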