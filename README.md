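# confens

Conformational-ensemble analysis for intrinsically disordered peptides.

Intrinsically disordered proteins (IDPs) have no single native structure;
what an experiment or simulation gives you is an *ensemble* of rapidly
interconverting conformations. Multisite phosphorylation of Ser/Thr adds
negative charge and new hydrogen-bonding capacity, and can compact, expand
or locally restructure such an ensemble. `confens` quantifies those changes
from multi-model coordinate files (one MODEL per frame), without requiring
access to the underlying molecular-dynamics engine:

- **Global dimensions** — mass-weighted radius of gyration *R*<sub>g</sub>,
  end-to-end distance *R*<sub>ee</sub> (CA–CA of the terminal residues),
  kernel-density distributions, and the shape factor

  *r*<sub>s</sub> = ⟨*R*<sub>ee</sub>²⟩ / ⟨*R*<sub>g</sub>²⟩,

  which is ≈ 6 for an ideal Gaussian coil and ≈ 12 for a stiff rod.
  Statistical errors come from Flyvbjerg–Petersen block averaging, because
  trajectory frames are strongly autocorrelated.
- **Secondary structure** — an in-house DSSP assignment based on the
  Kabsch–Sander hydrogen-bond energy
  *E* = 0.084·332·(1/r<sub>ON</sub> + 1/r<sub>CH</sub> − 1/r<sub>OH</sub> −
  1/r<sub>CN</sub>) kcal/mol (bond if *E* < −0.5), extended with
  polyproline-II detection: coil residues with (φ, ψ) within −75°±29°,
  +145°±29° in runs of ≥ 2 are labelled P. Profiles group classes as
  helix = H+G, strand = E+B, turn, bend, PPII and irregular.
- **Interactions** — residue–residue contact maps (any two heavy atoms
  within 0.4 nm) and phosphorylation delta-maps; salt-bridge probabilities
  between basic donors (Arg NE/NH1/NH2, Lys NZ, the N-terminal amine) and
  phosphate oxygens using the angle-dependent hydrogen-bond criterion
  r<sub>DA</sub> < 0.33 nm − 0.00044 θ²; and Arg–Tyr cation–π
  probabilities (guanidinium centre within 0.6 nm of both tyrosine CG and
  CZ). Error bars are standard errors across replicates.
- **Free-energy landscapes** — frames are superposed on the medoid
  ("central") structure, backbone Cartesian coordinates are decomposed by
  PCA (with a basis shared between the two variants so their landscapes
  are directly comparable), and *F* = −ln(*p*/*p*<sub>max</sub>) in RT
  units is estimated over (PC1, PC2) by Gaussian KDE. Basins, their
  populations and representative frames are extracted by steepest descent
  on the grid.
- **Synthetic ensembles** — freely-jointed chains and rigid rods with
  exact polymer statistics, ideal-dihedral peptide builders (α, 3₁₀, PPII,
  extended, β-sheet fixtures), interaction fixtures at controlled
  distances, and multi-state mixtures with known populations. Every
  analysis stage is validated against these ground truths.

## Worked example

```python
from confens import *
from confens.synthetic import *
from confens.compare import PhosphoComparison, ComparisonConfig

# 1) the two analytic reference shapes
coil = generate_gaussian_chain(ChainSpec(101, 0.38, 10_000, seed=1))
sf = shape_factor_from_ensemble(coil)
print(f"coil rs = {sf.rs:.2f} +/- {sf.error:.2f}")
rod = generate_rigid_rod(ChainSpec(1001, 0.38, 1, seed=0))
print(f"rod  rs = {shape_factor_from_ensemble(rod).rs:.3f}")

# 2) a two-variant comparison on a synthetic two-state peptide ensemble
seq_n = list("SSEEKFLRRI")                      # non-phosphorylated
seq_p = ["SEP", "SEP"] + list("EEKFLRRI")       # phosphoserines at 1-2
helix_coil = BackboneGeometry(phi=(-57.,)*5 + (-75.,)*5,
                              psi=(-47.,)*5 + (145.,)*5)
ppii = BackboneGeometry.ppii(10)
nonphos = generate_multistate_ensemble(
    [build_backbone(seq_n, helix_coil), build_backbone(seq_n, ppii)],
    (0.6, 0.4), noise_sd=0.03, n_frames=2000, n_replicates=4, seed=1)
phos = generate_multistate_ensemble(
    [build_backbone(seq_p, helix_coil), build_backbone(seq_p, ppii)],
    (0.4, 0.6), noise_sd=0.03, n_frames=2000, n_replicates=4, seed=2)

results = PhosphoComparison(nonphos, phos,
                            ComparisonConfig(landscape_grid=150)).fit()
print(results.summary())
results.save_tables("results/")   # CSV tables + schema-validated report.json
```

Output:

```
coil rs = 5.94 +/- 0.06
rod  rs = 11.976

Two-variant conformational-ensemble comparison
===============================================

Global dimensions (mean +/- block error):
  nonphos  Rg = 0.737 +/- 0.003 nm   Ree = 2.276 +/- 0.009 nm   rs = 9.55 +/- 0.10
  phos     Rg = 0.791 +/- 0.003 nm   Ree = 2.442 +/- 0.009 nm   rs = 9.55 +/- 0.09

Mean secondary-structure content (fractions):
  nonphos  helix=0.191  strand=0.001  turn=0.038  bend=0.066  ppii=0.106  irregular=0.599
  phos     helix=0.129  strand=0.000  turn=0.024  bend=0.043  ppii=0.127  irregular=0.677

Free-energy basins (population, min F in RT):
  nonphos  basin 0: pop=0.599 Fmin=0.96 RT (<=1RT)
  nonphos  basin 1: pop=0.399 Fmin=0.00 RT (<=1RT)
  phos     basin 0: pop=0.602 Fmin=0.00 RT (<=1RT)
  phos     basin 1: pop=0.394 Fmin=1.88 RT (<=2RT)
```

Reading this: the coil and rod hit their closed-form shape factors
(6(N+1)/(N+2) = 5.94 at N = 100 bonds; 12N/(N+2) = 11.976 at N = 1000).
The synthetic "phosphorylated" variant was generated with more weight on
the extended PPII conformer, and the pipeline recovers exactly that: a
larger *R*<sub>g</sub>/*R*<sub>ee</sub>, less helix, more PPII, and a
free-energy landscape whose extended-state basin (≈ 0.60 of frames, the
generator used 0.6) is now the global minimum. Basin populations match
the generation weights to within sampling error.

The same analyses are available from the shell (`confens simulate`,
`dimensions`, `sstruct`, `contacts`, `saltbridges`, `cationpi`,
`landscape`, `compare`); see `confens --help`.

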