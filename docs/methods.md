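# Methods

## The model

`macpol` implements a deterministic reaction-network model of macrophage
polarization.  The state vector holds molecule counts per cell (secreted
species: molecules per cell-equivalent volume of medium at 10⁶ cells/ml);
time is in hours.  Three signaling arms are integrated in one network and
are always simultaneously active:

- **IFN-γ arm.**  Extracellular IFN-γ ligates its receptor (reversibly),
  the complex is activated by association with JAK, and the activated
  complex catalytically phosphorylates STAT1.  pSTAT1 dimerizes, the dimer
  shuttles into the nucleus, and nuclear pSTAT1 transcribes IRF-1, SOCS1,
  SOCS3, CXCL10 and (directly or via IRF-1) the M1 markers iNOS, TNFα,
  IL-12 and CXCL9.  The IFN-γ receptor is not internalized; the activated
  complex turns over by a recycling step that degrades the ligand.
- **IL-4 arm.**  IL-4 receptor complexes additionally internalize and
  recycle.  Activated (and only surface) complexes phosphorylate STAT6;
  nuclear pSTAT6 drives IRF-4, PPARγ, SOCS1 (but not SOCS3), MRC1 and the
  M2 markers Arg-1 and IL-10.  The complexes also activate AKT in one
  step; pAKT promotes IL-10 and is deactivated by PTEN.  IL-13 input is
  treated as IL-4 (functional equivalence at the shared receptor).
- **Oxygen/HIF arm.**  PHD and FIH are lumped into one species that binds
  O₂ reversibly to form the active hydroxylase.  HIF-1α and HIF-2α are
  hydroxylated by it (blocked by ROS), the hydroxylated forms are degraded
  with a de-ubiquitination escape for HIF-1α, and the surviving α subunits
  dimerize with HIF-1β in the nucleus.  Nuclear HIF-1 transcribes VEGF,
  iNOS, PHD (negative feedback) and autocrine IFN-γ; nuclear HIF-2 drives
  Arg-1; PPARγ couples the IL-4 arm to HIF-2α synthesis.  Oxygen is a
  buffered species whose value is percent O₂ (21 = normoxia), mapped
  linearly — the simplest mapping consistent with stating conditions only
  as percentages.

Cross-talk is carried by SOCS1/3 (sequestration of activated receptor
complexes of both arms), STAT6-driven destabilization of IRF-1 mRNA (the
IL-4 → IRF-1 antagonism), IFN-γ-driven suppression of miR-3473b (which
de-represses PTEN and thereby lowers pAKT), TNFα-driven suppression of
miR-93 (which de-represses IRF-9 and HIF-1α mRNA), and the IRF-9 → IRG-1 →
itaconate → ROS → PHD loop.  miRs bind their target mRNAs and induce
target degradation with the miR recycled.

Rate laws are restricted to four kinds: irreversible and reversible mass
action, and Hill activation/inhibition (`V·Xⁿ/(Kⁿ+Xⁿ)`,
`V·Kⁿ/(Kⁿ+Xⁿ)`); Hill coefficients default to 1 (Michaelis-type
saturation, the weakest assumption) and every Hill reaction in the shipped
network uses n = 1.  Catalytic modifiers multiply rates linearly and are
never consumed.  For Hill-modulated conversions (e.g. PHD-dependent
hydroxylation inhibited by ROS) the Hill factor multiplies the mass-action
term of the reactants, which preserves positivity.

## Provenance of the shipped network

The network is a reconstruction: its wiring follows the published
mechanistic description of this polarization model, and it is engineered
to the published structural counts — 80 nodes from 34 unique species
groups and 130 reactions — with every parameter label quoted in the
published sensitivity ranking present and attached to the reaction that
ranking describes (e.g. `kf8` IL-4/receptor binding, `kf63`
STAT1/activated-receptor binding, `kf70/kr70` PHD/O₂ binding, `k127`,
`k61`, `k33` the IFN-γ, HIF-1α and IRF-1 production steps).  The original
deposited rate constants and initial conditions are not redistributable
tables, so the shipped values are order-of-magnitude estimates chosen on
physiological scales (receptors ~2×10³/cell, STATs ~10⁵/cell, mRNAs
10⁰–10²/cell, signaling on sub-hour to day timescales) and calibrated only
against the network's documented *qualitative* behaviors: transient
STAT1/STAT6 phosphorylation peaks, SOCS overexpression blunting them,
mutual IFN-γ/IL-4 antagonism at IRF-1 and pAKT, and hypoxia raising both
iNOS and Arg-1.  Quantitative trajectories are therefore not predictions
of the original model, and no numeric time-course is asserted anywhere in
the tests.

Several bookkeeping simplifications keep the network at its stated size:
receptor, JAK, STAT1, STAT6, AKT and HIF-1β pools are conserved cycles
(no synthesis/degradation on the signaling timescale), SOCS binding of
receptor complexes is reversible sequestration without a separate
complex-degradation channel, and four marker transcripts (IL-12, CXCL9,
CXCL10, MRC1 at the mRNA level where noted) are tracked with a reduced
mRNA/secreted-pool split.  SOCS-containing complexes are assigned to their
SOCS species group so that silencing a SOCS gene zeroes every molecular
form containing it.

## Baseline, priors and admissibility

Every simulation starts from the steady state of the untreated normoxic
model, found by long-horizon stiff integration until
max|dX/dt| / max(X) < 10⁻⁸ per hour (the convergence criterion is this
package's choice).  Basal tone — low autocrine IFN-γ driven by basal
nuclear HIF-1, and a small basal IL-4 source — keeps every one of the 34
group totals strictly positive, so fold-change normalizations are always
defined.  The copy-number prior table holds round literature-scale values
per group; the admissibility check requires each equilibrated group total
to lie within 0.5×–2× of its prior, and the calibration objective adds a
penalty quadratic in log-distance outside that band (a strict-rejection
mode exists for the literal pass/fail check).  Because the shipped rate
constants are a reconstruction, the prior table was finalized against the
calibrated baseline itself; the machinery — not agreement with external
measurements — is what the admissibility test certifies.

## Simulation engine

`scipy.integrate.solve_ivp` with LSODA (stiff-capable) at rtol 10⁻⁶ /
atol 10⁻³ molecules by default (both configurable).  Stimulus events
*add* the converted dose to the current ligand pool (sequential-dosing
protocols add a second stimulus without media change); oxygen events set
the buffered O₂ species.  Integration restarts at each event time and the
output grid always contains the event times.  Negative-state policy:
rates are evaluated on max(state, 0); transient undershoots smaller than
10⁻⁹ × max(state) are clamped to zero at segment boundaries, larger ones
raise an integration error.

## Perturbation semantics

- overexpress: target group's initial levels ×50 (configurable), all
  rates unchanged;
- silence: initial levels 0 and the primary rate of every reaction that
  synthesizes a group member from outside the group set to 0 — the target
  is then identically zero in any scenario;
- production_scale f: those same production rates ×f (f = 0.1 is the
  "90% production inhibition" convention);
- rate_scale f: one named rate constant ×f (f = 0.1 is the "90% binding
  inhibition" convention);
- initial_scale f: initial levels ×f only.

Edits are order-independent; two edits touching the same rate constant
raise instead of silently composing.  The M1/M2 score multiplies the six
M1 marker levels and divides by the product of the three M2 marker levels
at the evaluation time (default 24 h), on raw copy-number scale: the
score is a ratio, so baseline scales cancel when conditions are compared.
The six-M1/three-M2 panel membership is an inference from the marker set
tracked across the perturbation analyses (iNOS, TNFα, IL-12, CXCL9,
CXCL10 at mRNA level, IFN-γ / Arg-1, IL-10, VEGF); panels are arguments
everywhere they are used.

## Sensitivity analysis

Latin-hypercube samples (scipy's `LatinHypercube`) are mapped through
per-parameter log-uniform ranges, by default ×/÷10 around nominal (the
range is a config field; the source analyses do not state theirs).  PRCC
for parameter j is the Pearson correlation of the residuals of rank(xⱼ)
and rank(y) after least-squares regression of both on the ranks of all
other parameters (average ranks for ties); the p-value uses the t
statistic with n − 2 − (p − 1) degrees of freedom.  Significance is raw
p < 0.05; a Benjamini–Hochberg option exists but is off by default.
Failed simulations at extreme samples are dropped and counted, and the
analysis aborts if more than 5% fail.  Full-model runs in the shipped
tests and the acceptance script are scaled down (tens of samples, a
ten-label subset, the nominal baseline reused across samples) so they
complete in about a minute; they check coefficient *signs* only.

## Calibration and uncertainty

The objective is Σ over datasets of weight × Σ over points of
(normalized simulation − normalized observation)², each dataset simulated
under its own scenario and normalized by its own convention (to-max,
to-t0, to-untreated, to-reference-time, log2 fold).  Weights default to
1/n_points per dataset, equalizing dataset influence.  Simulation
failures contribute a large finite penalty so direct search continues.
The optimizer is a compass/pattern search on log-scaled parameters:
poll ±each coordinate on the current mesh, accept strict improvements,
expand the mesh ×2 on success and contract ×0.5 on failure, stop when the
mesh underflows; it is derivative-free, bound-respecting and
deterministic given its start, with seeded log-uniform multistarts
(3 by default) on top.  Bootstrap uncertainty resamples *datasets* with
replacement (points within a series are correlated, so the series is the
exchangeable unit), refits the free subset per replicate (50 replicates
and an 11-label high-sensitivity subset in the full-model workflow), and
can jitter each replicate's start log-normally so that directions the
data do not constrain keep their displaced values — making practical
non-identifiability visible as replicate spread.

## Synthetic data and the registry

The toy-network generator provides four topologies with attached
references: production/degradation (closed-form steady state s/d and
exponential relaxation), a linear catalytic cascade (closed-form steady
state), a conserved cycle (exact conservation total) and a
ligand/receptor/STAT module with SOCS-like negative feedback (peak-then-
decay of the terminal phosphoprotein).  Synthetic measurements apply
multiplicative lognormal noise with a stated coefficient of variation
(expression data are positive and normalized, so the error scales with
the signal); the CV is verified distributionally in the tests.

The calibration registry mirrors the structure of the literature corpus
this model class is fitted to — 73 series / 415 points across the IFN-γ,
IL-4, hypoxia and co-stimulation arms, each with its scenario, observable,
time grid and figure-style normalization — but its *values* are generated
from the shipped model with seeded noise, because the literature numbers
are not redistributable.  Registry tests certify scale and machinery, not
agreement with the literature.

What passing these tests shows: the engine integrates the stated kinetics
correctly, the edit semantics are exact, the statistics match independent
oracles, and the network reproduces the documented qualitative biology.
What they do not show: agreement with any quantitative experimental
trajectory, behavior of real macrophage heterogeneity (one deterministic
average cell), media exchange/washout, or spatial effects.

## Numerical choices and limitations

- Equilibration: LSODA in 2000-h chunks, cap 2×10⁵ h; residual threshold
  10⁻⁸/h.
- Tie-break in pattern search: coordinates are polled in order, first
  strict improvement within a sweep is kept; deterministic.
- PRCC of a constant parameter column is undefined and reported as NaN.
- SBML: writes Level 3 Version 1 core with MathML kinetic laws plus a
  namespaced annotation carrying the rate-law descriptor; reading our own
  documents is exact, and plain mass-action documents from other tools
  are interpreted from their MathML, with a definition error for kinetic
  laws outside that family.  Local parameters are promoted to global on
  read.
- Stochastic (SSA) simulation and spatial modeling are out of scope; the
  deterministic average suffices for the population-level readouts the
  model targets.
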