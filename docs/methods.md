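# Methods

This note documents the models, conventions, defaults and numerical choices
behind each stage of the package, what the synthetic generators do and do not
emulate, and the known limitations.

## Reaction-geometry screening

**Features.** For a docked acceptor pose against a glucosyl–enzyme conjugate,
`d1` is the Euclidean distance from a candidate hydroxyl oxygen to the
glucosyl anomeric carbon, `d2` the minimum distance from that hydroxyl oxygen
to the (one or two) carboxylate oxygens of the catalytic glutamate, and `a1`
the angle at the anomeric carbon subtended by the hydroxyl oxygen and the
aspartate ester (leaving-group) oxygen. `a1` is an in-line-attack proxy: the
chemically standard near-attack reading of "the angle between the hydroxyl
group and the glucose moiety". Because other atom choices are defensible, the
three site atoms are fully configurable through `CatalyticSiteMap`
(residue-number/atom-name selectors) rather than hard-coded.

**Criteria.** Defaults are `d1 < 4 Å`, `d2 < 4 Å`, `80° < a1 < 140°`, strict
inequalities (a pose exactly on a boundary is non-reactive); a `strict=False`
switch gives the closed-interval variant. `d2` uses the minimum over the
supplied carboxylate oxygens — the literal reading of "any oxygen atom of the
carboxylic group".

**Hydroxyl detection.** An oxygen is a hydroxyl if it has a bonded hydrogen
(distance below the covalent-radius sum + 0.4 Å). In hydrogen-free
structures, an oxygen qualifies when its single heavy neighbour is a carbon
at single-bond distance; a C–O contact under 1.28 Å is treated as a carbonyl
and excluded. This is a geometric heuristic, not a perception of bond orders;
ethers (two heavy neighbours) and carboxylates are excluded by construction.
Atoms belonging to standard amino-acid residues inside a docking MODEL
(flexible receptor side chains) are never counted as ligand hydroxyls.

**Pose verdict.** A pose with several hydroxyls is reactive if *any* one
satisfies all criteria — any transfer-competent hydroxyl enables the
reaction. The reported features belong to the representative hydroxyl:
minimal `d1` among criteria-satisfying hydroxyls when any exist, otherwise
minimal `d1` overall; ties break by smaller `d2`, then atom serial. Site-map
selectors resolve against the pose first and the rigid receptor second, so
flexible-side-chain docking output (flexible residues written into each
MODEL) and fully rigid receptors are handled by the same code path. Every
docking MODEL counts as one conformation; no best-model filtering is applied
by default.

## Ensemble comparison

Poses are mapped onto the `(d1, a1)` plane after discarding poses with
`d2 ≥ 4 Å` (the prefilter mirrors how the conformational maps are defined).
Default bins are 0.25 Å for `d1` over [0, 15] Å (the top edge extends in
whole bins if the data exceed 15 Å, so binning is always exhaustive) and 5°
for `a1` over [0, 180]°; these widths place the 4 Å / 80–140° reactive box
exactly on bin edges. Bins are half-open `[lo, hi)` with the last bin closed
(numpy's histogram convention). The comparison object is
`normalized(mutant) − normalized(WT)`, each variant's histogram normalized to
unit mass, so the difference sums to zero and swapping variants negates it
exactly. Gaussian smoothing (sd = 1 bin) exists for *plotting only* — every
statistic uses raw counts.

The **enrichment count** is the raw difference in reactive-pose counts
(mutant − WT). The per-ligand population summary adds a two-proportion
z-test; this inferential layer is an extra diagnostic, not part of the
original readout, and degenerates to p = 1 when both variants have zero (or
all) reactive poses.

## Flexibility

RMSF is computed per replica: every frame is least-squares superposed
(Kabsch, via SVD) onto the **first frame** over the selection, and
`RMSF_i = sqrt(mean_frames |r_i − ⟨r_i⟩|²)` uses the post-superposition mean
position. The selection defaults to one designated atom per residue (`CA`),
the standard per-residue convention; mass-weighting is not applied. Replicas
are averaged arithmetically with a 95% Student-t interval at
`df = n_replicas − 1`. Variants are compared residue-by-residue with
**Welch's** unequal-variance t-test on the per-replica RMSF values — the
safer default where only "t-test" is conventional — and no multiple-testing
correction is applied by default (per-residue significance is reported as
such); Benjamini–Hochberg adjustment is available behind a flag. Residues
where the two variants are numerically identical get p = 1 rather than NaN.
RMSD traces use the same superposition machinery against a reference frame
or explicit coordinates.

## Kinetics

Units are fixed package-wide: `[S]` in mM, `v` in µmol·min⁻¹·mg⁻¹, `kcat` in
min⁻¹, `kcat/Km` in mM⁻¹·min⁻¹.

- **Lineweaver–Burk**: OLS of `1/v` on `1/[S]` (≥ 3 distinct concentrations,
  strictly positive velocities). `Vmax = 1/intercept`, `Km = slope/intercept`;
  standard errors by the delta method from the coefficient covariance. A
  nonpositive intercept raises "no saturation detectable".
- **Nonlinear**: `scipy.optimize.curve_fit` on `v = Vmax·[S]/(Km+[S])`,
  initialized from the LB estimates. On noiseless data both routes agree to
  machine precision; under multiplicative noise the reciprocal transform
  amplifies low-velocity errors, so the nonlinear route is the recommended
  estimator (the test suite verifies its RMSE is no worse).
- **Linear regime**: when saturation is not reachable over the accessible
  concentration range, `kcat/Km` comes from a through-origin OLS of `v` on
  `[S]` (`v = 0` at `[S] = 0` is mechanistically forced; a free-intercept
  variant exists for diagnostics). A significant quadratic term (t-test at
  0.05) adds a curvature warning that the data are leaving the linear regime.
- **Turnover**: `kcat = Vmax · MW · 10⁻³` requires the enzyme molar mass as a
  user input; it is not derivable from specific activities. The demo and
  tests use the value implied by the reported kcat/Vmax pair
  (6.574/0.090 × 10³ ≈ 73 044 g/mol); the WT and mutant sucrose pairs imply
  the same mass within 1%, which the suite asserts as a data-consistency
  check. Replicates are fitted pooled; per-replicate fits are possible by
  subsetting the dataset.
- **Fold change**: `a/b` with first-order error propagation
  `sd = |a/b|·sqrt((sd_a/a)² + (sd_b/b)²)`, reported both at full precision
  and at the conventional 1-decimal rounding.

## Synthetic generators: what they emulate, and what they do not

**Pose ensembles.** The generator emulates the *output* of ensemble docking,
not the docking search: each pose's `(d1, d2, a1)` are drawn from configurable
Gaussians (defaults d1 ~ N(5, 2) Å, d2 ~ N(4, 1.5) Å, a1 ~ N(110°, 25°) —
a broad cloud around the catalytic site with a realistic minority of reactive
poses). Geometry is constructed invertibly: anomeric carbon at the origin,
ester oxygen on +y, the hydroxyl solved from `(d1, a1)` at a uniform random
azimuth, and the glutamate carboxylate placed along the outward radial at
exactly `d2` (OE1) and `d2 + 2.2 Å` (OE2), written into each MODEL as
flexible-side-chain docking engines do. Draws that are geometrically
degenerate (nonpositive distances, angles outside (0°, 180°)) are resampled,
not clamped. With `fraction_reactive_target` set, each pose's label is a
Bernoulli draw and its features are sampled from the spec distributions
truncated inside/outside the reactive box, making the downstream reactive
count exactly binomial. Extra hydroxyls are parked > 25 Å from the site so
the designated hydroxyl is always the representative. Not emulated: docking
scores' correlation with geometry (scores are uniform decoys), sterics,
receptor conformational coupling, solvent. Passing tests therefore certify
the *measurement and comparison machinery*, not any docking engine.

**Trajectories.** Residues fluctuate as iid Gaussians about a fixed
reference (one CA per residue, 50 ps frame spacing), so RMSF has the closed
form σ√3 and the replica-aggregation and testing layers can be calibrated
exactly. Not emulated: autocorrelation in time, collective motions, rigid-
body drift (superposition is still exercised by dedicated tests that inject
rigid motion). Real-trajectory RMSF magnitudes depend on force field and
sampling; nothing here asserts them.

**Kinetics.** Velocities are exact Michaelis–Menten values times
`(1 + ε)`, `ε ~ N(0, cv)` (the rare nonpositive draw is resampled);
replicates are independent. The default assay designs mirror the study
conditions: sucrose 0.4–200 mM and acceptor 0.1–1.0 mM ladders, triplicate,
5% CV. The acceptor design barely reaches `[S]/Km ≈ 0.4` at `Km = 2.718 mM`,
so Km is weakly identified there — visible in the recovery statistics (median
relative Km error ≈ 15% for that design alone vs ≈ 5% for the sucrose
design; the headline recovery statistic pools both designs). That weakness is
a property of the assay window, not of the estimator.

## Problem sizes and reproducibility

The bundled analysis uses 1000 poses per ligand/variant, 5 replicas × 200
frames × 50 residues for flexibility, triplicate kinetics, 200 seeds for
recovery statistics and 500 simulated replica sets for the null calibration —
sizes chosen so the full chain and the acceptance script each run in well
under a minute while keeping Monte-Carlo error far below the tested
tolerances. Every random operation takes an explicit seed (one RNG stream per
generator call, seeded from the spec); task seeds in the pipeline derive from
the base seed by a CRC of the task name. The pipeline manifest records the
seed, the config and SHA-256 digests of all outputs; rerunning the same
config reproduces every output byte-identically.

## Known limitations

- PDB/PDBQT parsing covers the fixed-column dialects emitted by the common
  tools (including `REMARK VINA RESULT` scores, altloc reduction to the
  highest-occupancy conformer, insertion codes); mmCIF and compressed
  trajectory formats (XTC/DCD) are out of scope — an adapter seam exists via
  the `Trajectory` container, which any reader can populate.
- Hydroxyl detection is distance-based; unusual protonation states or metal
  coordination are not modelled.
- The two-proportion test treats poses as independent draws; docking poses
  from the same receptor conformation are not truly independent, so its
  p-values are an optimistic diagnostic.
- `a1`'s atom definition is a modelling choice (see above); alternative
  definitions require only a different site map.
- No QM reactivity estimates, hydrogen-bond energetics, docking re-scoring,
  inhibition or bi-substrate kinetic mechanisms.
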