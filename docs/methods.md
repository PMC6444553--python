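# Methods

## Model

The package automates relative free energy perturbation under a
dual-topology representation.  Both end-state molecules exist throughout
the simulation; the alchemical coordinate mixes their potentials linearly,
`U_i = (1−λ_i)U_A + λ_i U_B`.  Assumptions inherited from this choice:

- the two molecules do not interact (no nonbonded terms between the A and B
  blocks, no bonded term crossing the partition), so changing bond topology
  between the pair is legal;
- each ligand keeps its own intramolecular bonded terms in both states, so
  dummy molecules stay internally intact and experience no strain from
  "real" atoms;
- distance restraints between equivalent atoms always pair a real atom with
  an atom that is dummy in that end state, so the restraint energy cancels
  exactly from the end-state free energy difference and needs no
  correction.  This is asserted structurally on every built specification.

Simulations are assumed to run in a finite water droplet (spherical
boundary conditions): atoms beyond the sphere are tightly restrained
(200 kcal/mol/Å²) and excluded from nonbonded work, a boundary shell is
treated as restrained territory, and no cutoff applies to the alchemical
region.  The MD engine itself is out of scope — the package emits input
decks and consumes per-window energy samples.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| sphere radius | 25 | Å | encloses a typical binding site plus a 10–15 Å solvation patch |
| boundary shell width | 3 | Å | operational definition of "on the boundary" for neutralization/restraint bookkeeping; configurable |
| water clash cutoff | 2.4 | Å | heavy-atom overlap distance below which a grid water is deleted whole |
| water grid spacing | 3.1 | Å | cubic grid approximating bulk TIP3P density |
| restraint k / window | 2.0 / 0.0–0.2 | kcal/mol/Å², Å | equivalent-atom tether; energy ½k(d−0.2)² past the window |
| pairing cutoff | 0.25 | Å | greedy nearest-distance matching over pre-superposed poses, element identity required by default |
| λ windows | 51 linear | – | default transformation path; sigmoidal warp available for poorly overlapping endpoints |
| replicates | 10 | – | independent velocity seeds; SEM is computed across them |
| equilibration | 31 ps ramp + 100 ps free | ps | heat 0.1→298 K while releasing a 25 kcal/mol/Å² solute restraint |
| production | 10 ps / window, 1 fs step | – | 6.41 ns per leg with the defaults |
| temperature | 298 | K | kT via R = 1.9872×10⁻³ kcal/mol/K |
| BAR tolerance / max iterations | 1e-7 / 500 | kcal/mol | self-consistent iteration seeded from the overlap-sampling estimate |
| r_Born | sphere radius | Å | cavity radius of the Born charging correction; configurable and logged with results |

## Numerical choices

- **Zwanzig / OS / BAR** are computed in log space (`logsumexp`), so large
  ΔU values cannot overflow.  BAR iterates the exact identity
  `exp(−β(ΔG−C)) = ⟨f(β(ΔU_f−C))⟩_f / ⟨f(β(ΔU_r+C))⟩_r` at the
  variance-optimal `C = ΔG + kT·ln(n_f/n_r)`; the update map is exactly
  antisymmetric under swapping forward/reverse inputs, so
  `ΔG(A→B) = −ΔG(B→A)` holds to machine precision for equal sample counts.
  Bennett's asymptotic variance is available alongside the estimate, and a
  signed-residual function is exposed so the root can be verified
  independently of the iteration.  Non-convergence raises an error carrying
  the last iterate.
- **Sphere boundary is closed**: distance exactly equal to the radius
  counts as inside (deterministic tie-break).
- **Greedy atom pairing** sorts candidate pairs by (distance, index_A,
  index_B), making ties deterministic.
- **λ schedules**: the sigmoidal warp is
  `λ(t) = ½(1 + tanh(s(2t−1))/tanh(s))` with sharpness s = 2 and endpoints
  forced exact; spacing is strictly smaller at branch endpoints than at
  mid-branch.  A midpoint start (λ = 0.5) produces two branches, each of
  *n* windows, covering [0.5, 1] and [0.5, 0]; the two branch ΔG values
  combine as ΔG(0→1) = ΔG(0.5→1) − ΔG(0.5→0).  The per-branch reading of
  *n* is this package's convention.
- **Heating ramp discretization**: the 31 ps ramp is split into five stages
  of 1/2/4/8/16 ps with temperatures linear from 0.1 to 298 K and solute
  restraints 25/25/10/5/1 kcal/mol/Å²; only the endpoints and total length
  are externally prescribed, the stage layout is a package choice.
- **Degenerate inputs**: a single replicate reports SEM as undefined
  (never 0); zero-variance benchmark columns and |r| = 1 correlations are
  rejected or flagged rather than silently propagated; net-charge
  integrality uses a 1e-3 e tolerance to absorb rounding in published
  charge sets.
- **File dialects** (`.lib`, `.prm`, FEP stage file, energy-sample CSV,
  YAML ligand interchange) are plain text, documented in the module
  docstrings, and every writer round-trips through its reader to an equal
  structure.  Angles and torsions are enumerated deterministically from the
  bond graph rather than stored.

## Design decisions that were genuinely open

- **Stage decomposition.**  How many FEP files a leg uses is not
  standardized; the default is a single stage (charges and vdW interpolate
  together, softcore depth 20 kcal/mol on the dummy-state Lennard-Jones of
  both molecules), with an optional three-stage scheme (discharge A → vdW
  swap under softcore → charge B) for hard transformations.
- **Equivalent-atom pairing** uses greedy nearest-distance matching with
  element identity over the superposed input poses.  Poses are expected
  pre-aligned (docked or crystal); no maximum-common-substructure search is
  performed, and pair-list design is left to the user or an external tool.
- **Restraint convention.**  The half-harmonic is ½k(d−d₀)² with d₀ the
  window upper bound; publications often leave the factor of two implicit,
  so the form is stated here explicitly.
- **Regression axis.**  Benchmark OLS defaults to calculated as response
  versus experimental as predictor; the axis is a flag because the
  convention differs between studies and printed slopes generally do not
  reproduce from rounded table values.
- **MAE reference handling.**  For radial designs anchored on a reference
  ligand, the reference row can be counted as a zero-deviation point
  (flag), matching how anchored benchmark tables are usually summarized.

## What the synthetic data emulates — and what it does not

`gen_gaussian_work` draws forward work from N(ΔG + σ²/2kT, σ²) and reverse
work from N(−ΔG + σ²/2kT, σ²), the unique Gaussian pair satisfying the
Crooks fluctuation theorem; `gen_harmonic_pair` samples the λ-mixed 1-D
harmonic potential exactly at every window (the mixed potential is again
harmonic, so the Boltzmann distribution is a known Gaussian).  Both have
closed-form answers, which makes estimator bias measurable.

They deliberately omit what real MD samples have: autocorrelation in time,
slow conformational degrees of freedom, anharmonicity, and incomplete
equilibration.  Passing tests therefore demonstrate that the estimators
and their aggregation are implemented correctly, not that any particular
molecular system is converged; convergence diagnostics on real data remain
the replicate SEM and the forward/backward hysteresis.

The toy ligand generator produces superposed pairs with a shared core
(jitter < 0.05 Å) and distinct substituents, with integer net charge and a
complete parameter table — enough to exercise pairing, merging, file
round-trips and deck generation, but with no claim of chemical realism.
The toy protein generator emits residues with correct ionizable-group atom
names on a synthetic backbone, for the neutralization and solvation logic.

## Problem sizes used in the test and acceptance runs

Estimator validation uses n = 5000 Gaussian work samples per direction and
51-window harmonic legs with 10⁴ samples per window (4–6 replicate
generations), which complete in seconds while leaving Monte-Carlo error
bars small enough for 3-standard-error checks.  Benchmark statistics run
over the bundled tables exactly as printed (23, 16, 8 and 6 rows).

## Known limitations

- No multistate estimator (MBAR) across all windows simultaneously;
  adjacent-window BAR is the finest analysis.
- No automatic equilibration detection or statistical-inefficiency
  correction; samples are taken as given.
- Q-engine compatibility of the emitted text dialects is best-effort: the
  grammars are documented here and round-trip internally, but no engine
  run is performed.
- The neutralization step renames residues and logs the change; it does
  not add or move protons itself (hydrogen placement is upstream).
- pKa prediction, tautomer/protomer enumeration, charge derivation and
  membrane embedding are out of scope by design.
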