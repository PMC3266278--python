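# Methods

## Model

Networks contain `n_prot = 6` proteins.  Transcription factors may act as
monomers or as dimers: a topology is a set of dimers (unordered protein
pairs, homodimers allowed) plus signed regulatory edges from regulators to
target genes.  In dimeric networks (`f_dim > 0`) the dimers are the
regulators; in monomeric networks the monomers regulate directly.

Dynamics are mass-action dimerization plus Hill-function transcription:

* dimer `(i,j)`:  `dx_ij/dt = k_on x_i x_j − k_off x_ij − γ_dim x_ij`
* monomer `i`:  `dx_i/dt = Σ_k Hill_ik(x_k) − γ_mono x_i − Σ_d (k_on x_i x_p − k_off x_d)`

with `Hill = b·x/(K+x)` for activation and `b·K/(K+x)` for repression,
cooperativity fixed at 1.  Production from multiple regulators is additive
(independent Hill terms, one `(b, K)` pair per edge).  Dimer *decay*
removes the complex without returning monomers; *dissociation* returns
them.  A homodimer consumes two copies of its monomer, so its net
association flux enters the monomer equation twice (a convention the model
description leaves open).

Parameter ranges (units as used throughout): `γ_mono = 0.2 /min`,
`γ_dim = 0.01 /min`, `k_off = 0.01 /min`, `k_on ∈ {0.01, 1} /(nM·min)`
(drawn per realization), `b ~ U[40, 2400] nM/min`, `K ~ U[10, 1000] nM`.
Initial monomer concentrations are uniform in `[1, 100] nM`, dimers start
at 0, and the horizon is 15,000 min.  The end state is reported always; a
convergence flag (`max |dx/dt|/(|x|+1 nM) < 1e-6 /min`) records whether it
is a steady state, and ensemble summaries report the flagged fraction
(> 99% of runs converge).

## Topology sampling

Each of the `n(n+1)/2` candidate dimers is included with probability
`f_dim`; each (regulator, gene) pair carries an edge with probability
`f_regint / n_regulators`, making the expected in-degree `f_regint`; each
edge activates with probability `f_act`.  Genes left without a regulator
receive one edge from a uniformly chosen regulator (minimal repair — the
least density distortion among the options; whole-topology resampling
would bias toward dense networks).  If `f_dim > 0` but no dimer is
realized the draw is repeated.  Mutants are *not* re-repaired: a
regulatory retarget may legitimately strip a gene of its only regulator,
in which case that gene decays to zero — that is part of the mutation's
effect.

## Mutations

Both operators preserve interaction counts.  A **PPI mutation** replaces
dimer A–B with a dimer sharing one subunit and absent from the network
(A–A homodimer targets allowed); the new dimer inherits all regulatory
edges with their signs and Hill parameters.  A **regulatory mutation**
retargets one edge to a gene its regulator did not yet regulate, keeping
sign and parameters.  The mutated interaction is chosen uniformly from the
exhaustive candidate list.  Monomeric networks admit only regulatory
mutations.

## D_mut

`D_mut = (1/n) Σ_i 2|C_wt,i − C_mut,i| / (C_wt,i + C_mut,i)` over all
species (monomers + dimers), with zero-denominator components contributing
0.  For a PPI mutant the swapped dimer is paired with its parent dimer
(the only bijection consistent with the mutation's bookkeeping).  The
metric is symmetric, bounded in [0, 2], invariant under joint
multiplicative rescaling and sensitive to log transforms.  Among the
scale-invariant candidates this mean symmetric relative difference is the
one that satisfies every calibration constraint and reproduces the
reference percentile ranges, but the choice is the package's single
largest modelling convention — quantitative comparisons carry a
correspondingly generous tolerance, and one qualitative finding is
sensitive to it (see Limitations).

Cutoffs: `D_small = 0.2`, `D_large = 1.0`, anchored by panel resampling of
expression tables (`expression_dmut`): 99th percentiles of interspecies
panel distributions bound "large", 1st percentiles of intraspecies ones
bound "small".  The synthetic generator (log-normal baseline, median
100 nM, shape 1.5; per-gene multiplicative log-normal divergence) carries
four divergence presets (0.70, 2.0, 0.28, 1.55) chosen once so its
percentiles match the four anchor values (≈0.92, ≈1.7, ≈0.1, ≈0.5)
reported for the real comparisons; the defaults lie between each pair.
What the generator does *not* emulate: correlated co-regulation between
genes, platform noise, or condition-specific scaling — passing tests show
the calibration arithmetic is right, not that these cutoffs are optimal
for any particular organism.

## Integration

The systems are stiff in the `k_on = 1` regime (association rates reach
`~1e4/min` against decay at `0.2/min`), so the production integrator is
LSODA (via `scipy.integrate.odeint`) at rtol = atol = 1e-10, initial step
0.01 min.  An adaptive explicit Runge–Kutta route (`method="rk45"`) and a
fixed-step RK4 oracle in the test suite cross-check the end states to
1e-4 relative agreement on converged runs; roundoff-level negative
concentrations (never below −1e-9 nM in practice) are clamped to zero,
anything worse marks the run failed.  Failed integrations are excluded
from ensemble statistics and logged per cell.

## Ensembles and statistics

* **set2** (robustness comparisons): all six `F_dim ∈ {0, 0.3, 0.6} ×
  F_regint ∈ {2, 4}` cells at `F_act = 0.5`, one kinetic draw per
  topology; wildtype + one PPI mutant (dimeric cells) + one regulatory
  mutant per network.  Default 500 topologies per cell; the acceptance
  script uses 1,600 (the full-scale design uses 25,000 — the desk-scale runs
  keep every other condition identical).
* **set1** (compensatory scan): `F_dim ∈ {0.3, 0.6}` at `F_regint = 2`
  crossed with `F_act ∈ {0.25, 0.5, 0.75}`, 20 topologies × many kinetic
  draws.  Primaries are random PPI mutations with `D_mut > D_large`; each
  receives `n_secondary` random secondary mutations per type, drawn with
  replacement from the mutant's candidate list (each distinct candidate is
  simulated once and reused across draws — identical results, far fewer
  integrations).  A secondary is compensatory when the double mutant lies
  within `D_small` of the *original wildtype*.  The scan can cap the
  number of primaries per activator fraction (deterministic subsample;
  the acceptance script caps at 150) to bound runtime; the rescue
  percentage is a per-secondary rate, so subsampling primaries only
  widens its standard error.

Significance uses the label-permutation test on the fraction of mutations
with `D_mut < D_small` (1,000 reshuffles, p = fraction of permuted
statistics at least as large, no smoothing).  Regulators are classed
pure-activator / pure-repressor / mixed by the signs of all their edges;
dimers carrying no regulatory edge are classed `none` and excluded from
sign comparisons.  The headline class means average per-cell means with
equal weight ("ensemble-averaged"); pooled-row statistics are reported
alongside.  Autoregulation counts and regulation entropy are computed on
the split graph (each dimer edge becomes two monomer-level branches, kept
as distinct parallel edges); paths are simple paths (the only terminating
reading in cyclic graphs), entropy is binary in bits.

Seeds: a master seed spawns per-(cell, network, draw, role)
`SeedSequence` children, so any network is independently regenerable and
reruns are bit-identical.

## Conservation kernels

DNA-contact residues: minimum heavy-atom distance to any DNA atom at a
10 Å cutoff (5 Å available; contact sets are nested by construction).
Conservation: per-column Shannon entropy over one-sequence-per-species
homolog sets, gaps excluded from counts and columns above 50% gaps
skipped.  Group comparison: two-sample Kolmogorov–Smirnov on pooled
per-residue entropies of contacting residues, with the same test on
non-contacting residues as control; per-protein means are also available.
Database acquisition (interaction databases, structure mapping, BLAST) is
out of scope; a synthetic fixture plants a conservation shift at the
contact positions of the "dimeric" group (substitution rate scaled by
`exp(-shift)`), with `shift = 0` making the groups exchangeable.

## Known limitations

* The D_mut expression is a chosen convention (above); absolute values
  are comparable only within it.
* Desk-scale ensembles (≤2,000 topologies/cell vs 25,000) leave the
  monomer-vs-dimer contrast with moderate statistical margin: at 500
  topologies/cell its randomization p is only ~0.05 at F_regint = 2; the
  p < 0.001 bound is met reliably from ~1,500 per cell, hence the
  acceptance script's 1,600.
* The compensatory-mutation rate is metric-sensitive and comes out low under
  this convention: ~0.5% of secondary regulatory mutations rescue a
  high-impact primary PPI mutation at `F_act = 0.75` (full-scale
  reference value ~3.5%), and the increase with `F_act` is not resolved at desk scale
  (single-digit rescue counts per cell).  Sensitivity: the rate is 1.3% /
  1.7% at rescue thresholds 0.3 / 0.4, and ~6% under a globally
  normalized divergence (`Σ|ΔC| / mean total`), which however misfits the
  regulator-class means that the per-component metric reproduces almost
  exactly.  The per-component definition is kept everywhere; the rescue
  statistic is reported as computed.
* The autoregulation analysis does *not* show the expected direction
  for PPI mutations: here mean D_mut
  decreases with the total autoregulation count for both mutation types
  (row-level and bin-mean Spearman, pooled and within cells).  The
  regulatory-mutation direction (robustness increases) comes out as
  expected.
  The likely causes are the D_mut convention's equal per-species
  weighting and the confounding of autoregulation count with realized
  dimer density, whose robustness benefit dominates at desk scale.  The
  corresponding check is left failing rather than redefined.
* Only cooperativity 1, additive multi-regulator production, and
  end-state (not time-course) comparisons are supported.
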