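# Methods

This note documents the models implemented in `pla2rank`, the parameters
that matter, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Surrogate molecular mechanics

The energy-balance ledger needs three molecular-mechanics quantities —
protein–ligand interaction energy, conformational strain, and a minimizer to
define the relaxed free state. The force field is a deliberately transparent
surrogate rather than a re-implementation of any proprietary class-II force
field:

* nonbonded: Coulomb `k_c·q_i·q_j/(ε·r)` with `k_c = 332.0637 kcal·Å/(mol·e²)`
  and Lennard-Jones 6-12 with Lorentz–Berthelot combination;
* bonded: harmonic bonds `E = k·(r−r0)²` (note: no ½ — stated here and in
  the code to avoid factor-of-two drift), harmonic angles `k·(θ−θ0)²`, and
  cosine torsions `(V/2)·(1+cos(nφ−φ0))` where `V` is the barrier height;
* exclusions: 1-2 and 1-3 intramolecular pairs excluded, 1-4 scaled by 0.5
  (configurable).

Defaults: constant interior dielectric ε = 4 (shared with the PB interior,
see below); a distance-dependent `ε·r` variant is provided because the
molecular-mechanics literature uses both. No cutoff by default — the systems
here are desk-scale — with an optional hard cutoff for larger fixtures.

**Consequence:** absolute energies from this surrogate are *not* comparable
to any published per-compound table. What the package reproduces is the
ledger arithmetic (δE1 = E_int + δE_prot + δE_lig; δE2 = δE1 + δE_solv), the
sign/ordering semantics, and the contracts (symmetry, rigid-motion
invariance, dielectric scaling, strain nonnegativity), which are
force-field-independent.

Element parameters (radius, LJ ε/σ, default charge) ship as an editable CSV
(`data/ff_parameters.csv`) so the parameterization is data, not code. Ca²⁺
carries its +2 formal charge by default. Ligand protonation follows the
binding mode of this chemotype: the oxadiazolone ring is anionic (net −1) by
default and overridable per run. Protein histidine protonation is an input,
not something the package decides.

The minimizer is steepest descent with Armijo backtracking: monotone
non-increasing energy across accepted steps by construction, terminating at
`max |∇E| ≤ tol` (default 0.01 kcal/mol/Å) or `max_steps` (default 5000,
with a warning flag). Gradients are central finite differences (h = 1e-5 Å);
at the sizes used here (≤ tens of atoms) this is cheaper to maintain than
analytic angle/torsion derivatives and accurate to well below the
convergence tolerance. Strain costs are evaluated against a re-minimized
free reference by default; nonnegativity holds only when the reference is a
true minimum of the shared surface, so loosely-converged references can
legitimately give small negative values.

## Finite-difference linearized Poisson–Boltzmann

The polar solvation energy is the reaction-field energy of the solute in a
dielectric continuum, computed on a cubic grid with a 7-point stencil:

* charges spread to the 8 surrounding nodes trilinearly (cloud-in-cell);
* the dielectric lives on cell faces; each inter-node segment is sampled at
  4 quadrature points and the face value is the harmonic mean of ε_in/ε_out
  weighted by the in-cavity fraction. The harmonic (series) average is the
  physically appropriate 1D combination; it smooths the staircase boundary
  and is what makes the Born-ion error decrease *monotonically* under grid
  refinement (the sharp midpoint rule oscillates);
* the cavity is the union of atomic spheres inflated by `probe_radius`
  (default 1.4 Å; no reentrant molecular-surface treatment — a documented
  simplification). For Born-ion validation the probe is 0 so the dielectric
  discontinuity sits at the bare radius the closed form assumes;
* Dirichlet boundary values are Debye–Hückel sums over the solute charges;
  a coarse 1.0 Å pass over a twice-larger box feeds boundary values to the
  requested fine spacing (one level of focusing);
* the linear system is solved by red–black successive over-relaxation with
  ω = 2/(1+sin(π/n)), converged to a relative per-sweep update below 1e-7;
  non-convergence raises an error carrying the residual;
* **self-energy cancellation:** the grid Green's function self-energy is
  removed by solving the identical grid and charge distribution a second
  time with a uniform interior dielectric and subtracting. This also cancels
  most of the discretization error dependence on sub-cell charge placement,
  which is why the result is stable (≪0.5%) under fractional-cell
  translations.

Defaults: ε_in = 4 / ε_out = 80, zero ionic strength (the 500 mM NaCl of the
enzymatic assay buffer is an experimental condition, not a continuum-model
input), grid ≥ 33 nodes per axis, solute extent ≤ 60% of the box edge
(enforced, and respected by the automatic box sizing). Validation: the Born
ion (q = 1e, R = 2 Å, ε 1→80) converges 2.06% → 1.29% → 0.035% at 1.0 / 0.5
/ 0.25 Å in a fixed 32 Å box against `−166.03·(1/ε_in−1/ε_out)·q²/R`;
charge scaling is quadratic to the solver tolerance; two far-separated ions
reproduce two Born energies plus the analytic screened cross-interaction
`k_c q₁q₂(1/ε_out−1/ε_in)/d`.

Because no grid, dielectric assignment or PB package is canonical for the
reference energy table, absolute solvation energies are not reproduction
targets; the anchored quantity is the balance
`δE_solv = E_solv(complex) − E_solv(lig) − E_solv(prot)` (positive = net
dehydration penalty), which is exact arithmetic.

## Energy-balance ledger and concordance

`EnergyLedgerRow` carries the nine per-compound energies; `validate_ledger`
checks the three identities per row at a tolerance of 0.05 kcal/mol
(one-decimal printed rounding) and that the isolated-protein solvation
energy is constant across rows sharing a protein. The shipped reference
table is kept verbatim; its C4 row fails the δE2 identity by 0.2 kcal/mol
(the printed total differs from the sum of its own printed components —
accumulated rounding in the source), and the validator reports exactly that
rather than the table being silently edited. All 24 identities hold at a
rounding-propagated tolerance of 0.25 kcal/mol.

Rank concordance is Kendall τ-b (tie-corrected, via `scipy.stats.kendalltau`)
with the fixed convention that more-negative δE2 and lower IC50 are both
"better", so concordance is positive τ on raw values. The report includes
concordant/discordant/tied pair counts and the discordant pairs by name, so
a "same ranking" claim is measured, not assumed: over C1–C8 the result is
τ-b = 0.837 with 2 discordant pairs (both involving C4) and one tie (C1/C3
at 5.0 µM). Censored potencies (">100 µM") are representable as open bounds
and excluded from concordance by default.

## Fragmental log P

Rekker's method: log P = Σ aₙ·fₙ over a fragment decomposition, plus named
proximity/conjugation corrections. Two declared assumptions:

* the fragmental-constant table (`data/rekker_fragments.csv`, version
  `chemotype-curated-1.0`) uses revised-Rekker-style values for the backbone
  fragments (CH₂ 0.519, C₆H₄ 1.688, C₆H₅ 1.902, aryl-ether O −0.450, …);
  no published constant exists for the 1,2,4-oxadiazol-5(4H)-one ring, and
  the ring and terminal aromatic group constants are curated group values
  internally consistent across this compound family;
* the eight compound definitions are curated fragment lists (JSON), not
  perceptions from SMILES, so every reported value is auditable fragment by
  fragment. A convenience decomposer exists for simple hydrocarbons/ethers
  (heavy atoms only; hydrogens are implicit in the CHₙ/C₆Hₙ keys, so bare
  benzene returns one C₆H₅), but the packaged numbers never depend on it.

The neutral species is evaluated (fragmental-method convention for
ionizable solutes). Additivity consequences are load-bearing and tested:
position isomers with equal fragment multisets (C2/C6) are exactly equal,
and one CH₂ insertion changes log P by exactly f(CH₂).

## Assay statistics

* **Initial rate**: least-squares slope over the first 60 s of a
  fluorimetric trace (≥5 points enforced), reported per minute.
* **IC50**: 4-parameter logistic fit on log10-concentration with asymptotes
  fixed at 100/0 by default (the assay reports percent of uninhibited
  control and no fit model is canonical; a free-asymptote variant exists).
  The initial guess interpolates the 50% crossing on the log axis, which is
  why noise-free recovery is exact to the optimizer tolerance across
  [0.01, 100] µM. If activities never cross 50% within the tested range the
  result is censored at the top tested concentration — a numeric IC50 above
  the tested range is never reported.
* **Cellular reductions**: `%inhibition = 100 − 100·(treated/control)`,
  fold induction = treated/control (duality: 0% inhibition ⇔ fold 1), MTT
  viability = 100·(A570−A690)/(reference), Griess nitrite by OLS calibration
  and inverse prediction (negative predictions clamped to 0 and flagged),
  per-µg-protein normalization, and densitometry ratios rescaled so the
  reference group equals 1. Replicates aggregate as mean ± SEM with n
  recorded. Significance testing is deliberately outside the contract
  surface — standard Kruskal–Wallis/ANOVA routines are invoked by users,
  not reimplemented.

## Synthetic data

The generators provide every input the pipeline consumes, with the effect
sizes of the study conditions as defaults: per-medium PGE2 fold inductions
23.3 / 18.3 / 2.8 and nitrite 8.1 / 2.6 / 2.0 (DMEM, +0.1% BSA, +2% FCS);
C8 dose grids 0.31–1.24 µM (DMEM) and 0.31–4.96 µM (supplemented media); an
Emax dose-response on the IL-1β-induced PGE2 increment whose top doses bring
secretion back to about the untreated level; sub-micromolar IC50 magnitudes
for the kinetic traces; replicate counts of 3–8 (default 6) and 10%
multiplicative noise, giving replicate SEMs under ~10%. One global seed fans
out to named per-generator streams (`SeedSequence` + CRC of the consumer
label), so identical configs are bit-identical and modules are testable
independently.

What the generators do *not* emulate: real chondrocyte biology (no
covariance between markers, no plate/batch effects, no heteroscedasticity
beyond constant CV), real protein structure (toy complexes are jittered
lattices with chain-topology ligands — sufficient for pairwise-energy and
bookkeeping oracles, not for pose realism), and pharmacokinetics. Passing
tests therefore demonstrate that the *reductions and arithmetic* are
correct and stable under the stated noise, not that the pipeline would
reproduce wet-lab numbers.

## Problem sizes

The default validation sizes are chosen to keep every stage at desk scale:
Born grids up to 129³ nodes (0.25 Å in a 32 Å box), toy complexes of ~30
atoms, minimizer fixtures of ≤10 atoms, IC50 recovery over 20 log-spaced
truths, and fold-induction recovery at n = 1000 replicates.

## Known limitations

* The surrogate force field has no atom typing; bonded terms are explicit
  per-molecule topologies supplied by the caller or generator.
* The PB cavity has no reentrant (molecular-surface) treatment and no
  apolar/SASA term — the balance this package computes has no such term.
* The fragment decomposer covers simple hydrocarbon/ether/halide patterns
  only; heteroaromatic systems enter through curated group fragments.
* MD/frame selection, docking/pose generation and mmCIF input are out of
  scope; candidate geometries are inputs.
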