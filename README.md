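# asase

Post-simulation analysis for amylosucrase acceptor engineering: geometric
screening of ensemble-docking poses for glucosyl-transfer **reactive
conformations**, WT-vs-mutant conformation-space comparison, replica-averaged
per-residue flexibility (RMSF), and Michaelis–Menten kinetics — with
synthetic-data generators standing in for the MD and docking engines so the
whole pipeline runs on a desktop with known ground truth.

## The scientific problem

Amylosucrase (ASase, EC 2.4.1.4) transfers a glucosyl unit from sucrose onto
the hydroxyl group of an acceptor compound (transglucosylation). Engineering
variants with better acceptor specificity for small phenolics (e.g.
4-methylumbelliferone, hydroquinone) is of practical interest, and a standard
computational readout is the population of *reactive conformations* among
docked acceptor poses: poses whose hydroxyl geometry permits attack on the
glucosyl–enzyme intermediate.

For a docked pose, three features are measured at the catalytic site:

- **d1** — distance from the acceptor hydroxyl oxygen to the glucosyl anomeric
  carbon (the electrophile, covalently bound to the nucleophile aspartate);
- **d2** — minimum distance from the hydroxyl oxygen to a carboxylate oxygen
  of the catalytic glutamate (the general base);
- **a1** — attack angle at the anomeric carbon between the hydroxyl oxygen and
  the leaving-group (aspartate ester) oxygen.

A pose is **reactive** when `d1 < 4 Å`, `d2 < 4 Å` and `80° < a1 < 140°`
(strict inequalities; all thresholds configurable). Ensembles of such verdicts
are compared between a wild-type enzyme and a mutant as 2D `(d1, a1)` density
differences after a `d2 < 4 Å` prefilter, with the *enrichment count* = the
raw difference in reactive poses inside the reactive box.

Around that core, the package provides:

- **Ensemble bookkeeping** — `n_replicas × (sim_length/stride + [t₀])`
  conformations (5 replicas × 5 ns / 50 ps incl. t=0 → 505);
- **Flexibility** — per-residue RMSF per replica (Kabsch superposition,
  deviations about the post-superposition mean), replica means with 95% t
  confidence intervals, per-residue Welch tests between variants, RMSD traces;
- **Kinetics** — Lineweaver–Burk (`1/v` on `1/[S]`, delta-method SEs) and
  direct nonlinear fits of `v = Vmax·[S]/(Km+[S])`; through-origin linear
  regression for non-saturating assays (slope → `kcat/Km`);
  `kcat = Vmax·MW·10⁻³`; product-yield fold changes with propagated sd;
- **Synthetic generators** — pose ensembles with exact, invertible
  `(d1, d2, a1)` ground truth; trajectories of iid Gaussian fluctuation
  (closed-form RMSF = σ√3); Michaelis–Menten data with multiplicative noise.

## Worked example

The numbered scripts under `analysis/` run the complete study on synthetic
data (about 15 s total):

```bash
python analysis/01_generate_datasets.py --seed 0   # poses, trajectories, assays
python analysis/02_screen_poses.py                 # (d1, d2, a1) per pose
python analysis/03_conformation_maps.py            # WT vs mutant maps
python analysis/04_flexibility.py                  # RMSF with 95% CI + Welch tests
python analysis/05_kinetics.py                     # kinetic constants, fold change
```

With seed 0, screening 1000 poses per ligand/variant (generated at reactive
fractions 0.20 WT vs 0.30 mutant) prints:

```
ligand      enrichment (mut - WT reactive poses in the box)
  daidzein  +103
 genistein  +103
        hq  +98
kaempferol  +91
        mu  +86
direction of the mutant shift is consistent across acceptors
```

i.e. the mutant gains ~100 reactive poses per 1000 for every acceptor, the
same qualitative signature the geometric screen is designed to detect. The
flexibility stage reports the stiffened loop (residues 20–30, σ reduced ×0.6
in the mutant trajectories):

```
11 residues significantly less flexible in the mutant (alpha=0.05):
  residues: 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31
```

and the kinetics stage recovers the generating constants from noisy
triplicates, e.g. mutant/MU `Km = 2.73 ± 0.63 mM` (true 2.718) by the
nonlinear route, efficiency `6.26 mM⁻¹min⁻¹`, and the bioconversion yields
`6.80 ± 0.26` vs `4.76 ± 0.02 g/l` give a `1.4`-fold increase.

The same operations are exposed as a CLI
(`asase generate|validate|screen|compare|rmsf|kinetics|run`); `asase run`
executes the whole chain from a YAML config and writes a manifest with
SHA-256 digests of every output, byte-identical across reruns of the same
config and seed.

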